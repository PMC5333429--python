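"""CYP-dependence labeling of GSOM nodes and predicted interactions.

Drug interactions routed through cytochrome P450 enzymes (isoforms CYP1A2,
CYP2C9, CYP2C19, CYP2D6, CYP3A4) are clinically prominent, so predictions
are annotated by where they fall on the trained maps: an ambiguous node
inherits the union of the CYP isoform sets of its known interacting pairs
(CYP-Dependent if that union is non-empty), and negative nodes are
CYP-Independent.  A predicted pair combines its node labels across the two
maps by set union — the permissive reading.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .classification import EnsemblePrediction
from .pul_profiling import NODE_AMBIGUOUS, NODE_NEGATIVE, NodeProfile
from .similarity import POSITIVE, PairKey

CYP_DEPENDENT = "CYP-Dependent"
CYP_INDEPENDENT = "CYP-Independent"

ISOFORMS = frozenset({"CYP1A2", "CYP2C9", "CYP2C19", "CYP2D6", "CYP3A4"})


@dataclass(frozen=True)
class CYPLabel:
    dependence: str
    isoforms: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.dependence not in (CYP_DEPENDENT, CYP_INDEPENDENT):
            raise ValueError(f"unknown dependence tag {self.dependence!r}")
        if self.dependence == CYP_INDEPENDENT and self.isoforms:
            raise ValueError("CYP-Independent label cannot carry isoforms")
        if self.dependence == CYP_DEPENDENT and not self.isoforms:
            raise ValueError("CYP-Dependent label requires at least one isoform")


def validate_isoforms(names: Iterable[str], allow_extra: bool = False) -> frozenset[str]:
    """Check isoform names against the five-isoform vocabulary."""
    s = frozenset(names)
    unknown = s - ISOFORMS
    if unknown and not allow_extra:
        raise ValueError(f"unknown CYP isoforms: {sorted(unknown)}")
    return s


def label_node_cyp(
    profile: NodeProfile,
    known_cyp: Mapping[PairKey, frozenset[str]],
    labels: Mapping[PairKey, str] | None = None,
    allow_extra_isoforms: bool = False,
) -> CYPLabel:
    """CYP label for one ambiguous or negative node.

    Ambiguous nodes take the union of their known-positive members' isoform
    sets (CYP-Dependent if non-empty); negative nodes are CYP-Independent.
    Purely-positive nodes carry no unlabeled members to annotate and are
    rejected.
    """
    if profile.label == NODE_NEGATIVE:
        return CYPLabel(dependence=CYP_INDEPENDENT)
    if profile.label != NODE_AMBIGUOUS:
        raise ValueError(
            f"node {profile.node_id} has label {profile.label!r}; "
            "only ambiguous or negative nodes get CYP labels"
        )
    union: set[str] = set()
    for p in profile.member_pairs:
        if labels is not None and labels.get(p) != POSITIVE:
            continue
        if labels is None and p not in known_cyp:
            continue
        iso = known_cyp.get(p, frozenset())
        union |= validate_isoforms(iso, allow_extra=allow_extra_isoforms)
    if union:
        return CYPLabel(dependence=CYP_DEPENDENT, isoforms=frozenset(union))
    return CYPLabel(dependence=CYP_INDEPENDENT)


def label_map_cyp(
    profiles: Iterable[NodeProfile],
    known_cyp: Mapping[PairKey, frozenset[str]],
    labels: Mapping[PairKey, str],
    allow_extra_isoforms: bool = False,
) -> dict[PairKey, CYPLabel]:
    """Pair -> CYP label for all members of ambiguous and negative nodes."""
    out: dict[PairKey, CYPLabel] = {}
    for prof in profiles:
        if prof.label not in (NODE_AMBIGUOUS, NODE_NEGATIVE):
            continue
        node_label = label_node_cyp(
            prof, known_cyp, labels=labels, allow_extra_isoforms=allow_extra_isoforms
        )
        for p in prof.member_pairs:
            out[p] = node_label
    return out


def annotate_predictions(
    predictions: Sequence[EnsemblePrediction],
    node_labels_per_map: Sequence[Mapping[PairKey, CYPLabel]],
) -> pd.DataFrame:
    """Join predictions with per-map node CYP labels (union across maps).

    Every predicted pair must carry a label in each map; the result gains
    ``cyp_dependence`` and a semicolon-joined ``cyp_isoforms`` column.
    """
    rows = []
    for pred in predictions:
        union: set[str] = set()
        for k, labels in enumerate(node_labels_per_map):
            lab = labels.get(pred.pair)
            if lab is None:
                raise KeyError(f"pair {pred.pair} has no CYP node label in map {k}")
            union |= lab.isoforms
        dependence = CYP_DEPENDENT if union else CYP_INDEPENDENT
        rows.append(
            {
                "drug_a": pred.pair[0],
                "drug_b": pred.pair[1],
                "mean_posterior": pred.mean_posterior,
                "decision": pred.decision,
                "cyp_dependence": dependence,
                "cyp_isoforms": ";".join(sorted(union)),
            }
        )
    return pd.DataFrame(rows)
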