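"""Exception hierarchy for gsompul.

All errors derive from :class:`GsomPulError` so callers can catch the
package's failures with one ``except`` clause; most also derive from
``ValueError`` because they signal invalid inputs.
"""


class GsomPulError(Exception):
    """Base class for all gsompul errors."""


class DuplicateDrugError(GsomPulError, ValueError):
    """Duplicate drug identifiers where uniqueness is required."""


class DrugMissingError(GsomPulError, KeyError):
    """A drug identifier is absent from a feature source."""


class LengthMismatchError(GsomPulError, ValueError):
    """Two vectors that must be conformable have different lengths."""


class NonBinaryValueError(GsomPulError, ValueError):
    """A cell of a drug-feature matrix is not 0 or 1."""


class SelfPairError(GsomPulError, ValueError):
    """A drug paired with itself where only distinct pairs are allowed."""


class LabelConflictError(GsomPulError, ValueError):
    """The same drug pair carries two different labels."""


class EmptyMapError(GsomPulError, ValueError):
    """An operation requires a map with at least one node."""


class DegenerateInputError(GsomPulError, ValueError):
    """Input too degenerate for the requested fit (single class, zero variance...)."""
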