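"""Pairwise drug similarity feature construction.

Two drugs are each described by binary association profiles drawn from one
or more sources (chemical substructures, therapeutic classes, protein
targets, side effects...).  A candidate drug pair is turned into a feature
vector in one of two ways:

* **SFR1** — one Jaccard index per source: the overall overlap of the two
  drugs' profiles, giving a vector with as many components as sources.
* **SFR2** — the element-wise average of the two profiles, concatenated
  across sources.  On binary inputs every entry is 0 (feature in neither
  drug), 0.5 (in exactly one) or 1 (in both), so SFR2 preserves *which*
  features overlap, not just how many.

SFR2 vectors are high dimensional and sparse, so a variance-based PCA
projection (``fit_variance_projection``) is provided to compress them to
the leading components that retain a requested fraction of variance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import (
    DegenerateInputError,
    DrugMissingError,
    DuplicateDrugError,
    LengthMismatchError,
    NonBinaryValueError,
    SelfPairError,
)

PairKey = tuple[str, str]

POSITIVE = "positive"
UNLABELED = "unlabeled"


def pair_key(a: str, b: str) -> PairKey:
    """Canonical key for an unordered drug pair: lexicographically sorted tuple."""
    if a == b:
        raise SelfPairError(f"self-pair not allowed: {a!r}")
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class DrugFeatureMatrix:
    """Binary drug x feature association table for one source."""

    source_name: str
    drug_ids: tuple[str, ...]
    feature_ids: tuple[str, ...]
    values: np.ndarray  # shape (n_drugs, n_features), entries in {0, 1}

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.uint8)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if values.shape[0] < 1 or values.shape[1] < 1:
            raise ValueError("matrix needs at least one drug and one feature")
        if values.shape != (len(self.drug_ids), len(self.feature_ids)):
            raise ValueError("values shape does not match id lists")
        raw = np.asarray(self.values)
        if not np.isin(raw, (0, 1)).all():
            bad = np.argwhere(~np.isin(raw, (0, 1)))[0]
            raise NonBinaryValueError(
                f"non-binary cell at drug {self.drug_ids[bad[0]]!r}, "
                f"feature {self.feature_ids[bad[1]]!r} in source {self.source_name!r}"
            )
        if len(set(self.drug_ids)) != len(self.drug_ids):
            raise DuplicateDrugError(f"duplicate drug ids in source {self.source_name!r}")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError(f"duplicate feature ids in source {self.source_name!r}")
        object.__setattr__(self, "values", values)
        object.__setattr__(
            self, "_index", {d: i for i, d in enumerate(self.drug_ids)}
        )

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def row(self, drug_id: str) -> np.ndarray:
        """Binary profile of one drug; raises :class:`DrugMissingError` if absent."""
        idx = self._index.get(drug_id)  # type: ignore[attr-defined]
        if idx is None:
            raise DrugMissingError(
                f"drug {drug_id!r} missing from source {self.source_name!r}"
            )
        return self.values[idx]

    def __contains__(self, drug_id: str) -> bool:
        return drug_id in self._index  # type: ignore[attr-defined]


@dataclass(frozen=True)
class PairIndex:
    """Ordered universe of unordered distinct drug pairs, canonical keys."""

    pairs: tuple[PairKey, ...]

    def __post_init__(self) -> None:
        seen = set()
        for a, b in self.pairs:
            if a == b:
                raise SelfPairError(f"self-pair {a!r} in pair index")
            if a > b:
                raise ValueError(f"pair ({a!r}, {b!r}) not in canonical order")
            if (a, b) in seen:
                raise ValueError(f"duplicate pair ({a!r}, {b!r})")
            seen.add((a, b))

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def index_of(self) -> dict[PairKey, int]:
        return {p: i for i, p in enumerate(self.pairs)}


def enumerate_pairs(drug_ids: Sequence[str]) -> PairIndex:
    """All unordered distinct pairs over ``drug_ids``, count n(n-1)/2.

    Pairs are listed in lexicographic order of their canonical keys so the
    enumeration is independent of the input ordering.
    """
    ids = list(drug_ids)
    if not ids:
        raise ValueError("drug_ids must be non-empty")
    if len(set(ids)) != len(ids):
        dupes = sorted({d for d in ids if ids.count(d) > 1})
        raise DuplicateDrugError(f"duplicate drug ids: {dupes}")
    return PairIndex(tuple(itertools.combinations(sorted(ids), 2)))


def _check_binary_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise LengthMismatchError(
            f"vectors must be 1-D and equal length, got {a.shape} and {b.shape}"
        )
    return a, b


def jaccard_index(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard index |a AND b| / |a OR b| of two binary vectors.

    The pair of all-zero vectors has an empty union; its similarity is
    defined as 0 (no shared evidence is not evidence of similarity).
    """
    a, b = _check_binary_pair(a, b)
    for v in (a, b):
        if not np.isin(v, (0, 1)).all():
            raise NonBinaryValueError("jaccard_index requires binary vectors")
    au = a.astype(bool)
    bu = b.astype(bool)
    union = int(np.count_nonzero(au | bu))
    if union == 0:
        return 0.0
    return int(np.count_nonzero(au & bu)) / union


def individual_similarity(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Element-wise average of two profiles; on binary input yields {0, 0.5, 1}."""
    a, b = _check_binary_pair(a, b)
    return (a.astype(float) + b.astype(float)) / 2.0


def build_sfr1(pair: PairKey, matrices: Sequence[DrugFeatureMatrix]) -> np.ndarray:
    """One Jaccard value per source, in the supplied source order."""
    d1, d2 = pair
    return np.array(
        [jaccard_index(m.row(d1), m.row(d2)) for m in matrices], dtype=float
    )


def build_sfr2(pair: PairKey, matrices: Sequence[DrugFeatureMatrix]) -> np.ndarray:
    """Concatenated element-wise averages over sources; length = sum of dims."""
    d1, d2 = pair
    return np.concatenate(
        [individual_similarity(m.row(d1), m.row(d2)) for m in matrices]
    )


@dataclass(frozen=True)
class PairFeatureTable:
    """Per-pair similarity vectors plus positive/unlabeled PU labels."""

    representation: str  # "SFR1" | "SFR2" | "SFR2-projected"
    pairs: PairIndex
    vectors: np.ndarray  # shape (n_pairs, n_features)
    labels: tuple[str, ...] = ()
    source_names: tuple[str, ...] = ()
    source_dims: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        vectors = np.asarray(self.vectors, dtype=float)
        if vectors.ndim != 2 or vectors.shape[0] != len(self.pairs):
            raise ValueError("vectors must have one row per pair")
        labels = self.labels or tuple(UNLABELED for _ in range(len(self.pairs)))
        if len(labels) != len(self.pairs):
            raise ValueError("labels must have one entry per pair")
        bad = set(labels) - {POSITIVE, UNLABELED}
        if bad:
            raise ValueError(f"unknown labels: {sorted(bad)}")
        object.__setattr__(self, "vectors", vectors)
        object.__setattr__(self, "labels", tuple(labels))
        object.__setattr__(self, "_row", self.pairs.index_of())

    @property
    def n_features(self) -> int:
        return self.vectors.shape[1]

    def vector_for(self, pair: PairKey) -> np.ndarray:
        row = self._row.get(pair)  # type: ignore[attr-defined]
        if row is None:
            raise KeyError(f"pair {pair} not in feature table")
        return self.vectors[row]

    def matrix_for(self, pairs: Sequence[PairKey]) -> np.ndarray:
        rows = []
        for p in pairs:
            row = self._row.get(p)  # type: ignore[attr-defined]
            if row is None:
                raise KeyError(f"pair {p} not in {self.representation} feature table")
            rows.append(row)
        return self.vectors[np.asarray(rows, dtype=int)]

    def with_labels(self, label_map: Mapping[PairKey, str]) -> "PairFeatureTable":
        """Return a copy whose labels come from ``label_map`` (default unlabeled)."""
        labels = tuple(label_map.get(p, UNLABELED) for p in self.pairs)
        return PairFeatureTable(
            representation=self.representation,
            pairs=self.pairs,
            vectors=self.vectors,
            labels=labels,
            source_names=self.source_names,
            source_dims=self.source_dims,
        )

    def label_map(self) -> dict[PairKey, str]:
        return dict(zip(self.pairs, self.labels))


def _common_drug_order(matrices: Sequence[DrugFeatureMatrix]) -> list[str]:
    if not matrices:
        raise ValueError("at least one feature matrix required")
    common = set(matrices[0].drug_ids)
    for m in matrices[1:]:
        common &= set(m.drug_ids)
    if len(common) < 2:
        raise ValueError("fewer than two drugs shared by all sources")
    return sorted(common)


def build_pair_feature_table(
    matrices: Sequence[DrugFeatureMatrix],
    representation: str,
    pairs: PairIndex | None = None,
    chunk_size: int = 4096,
) -> PairFeatureTable:
    """Vectorized construction of the full SFR1 or SFR2 pair table.

    Drugs absent from any source are dropped before pair enumeration, so the
    pair universe is the intersection of the sources' drug sets.  Equivalent
    to calling :func:`build_sfr1` / :func:`build_sfr2` per pair.
    """
    if representation not in ("SFR1", "SFR2"):
        raise ValueError(f"unknown representation {representation!r}")
    drugs = _common_drug_order(matrices)
    if pairs is None:
        pairs = enumerate_pairs(drugs)
    pos = {d: i for i, d in enumerate(drugs)}
    idx_pairs = np.array(
        [(pos[a], pos[b]) for a, b in pairs], dtype=int
    ) if len(pairs) else np.zeros((0, 2), dtype=int)

    per_source = []
    for m in matrices:
        order = [m._index[d] for d in drugs]  # type: ignore[attr-defined]
        A = m.values[np.asarray(order, dtype=int)]
        cols = []
        for start in range(0, len(idx_pairs), chunk_size):
            ii = idx_pairs[start : start + chunk_size, 0]
            jj = idx_pairs[start : start + chunk_size, 1]
            ai = A[ii].astype(bool)
            aj = A[jj].astype(bool)
            if representation == "SFR1":
                inter = np.count_nonzero(ai & aj, axis=1).astype(float)
                union = np.count_nonzero(ai | aj, axis=1).astype(float)
                with np.errstate(invalid="ignore", divide="ignore"):
                    jac = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
                cols.append(jac[:, None])
            else:
                cols.append((ai.astype(float) + aj.astype(float)) / 2.0)
        per_source.append(
            np.vstack(cols) if cols else np.zeros((0, 1 if representation == "SFR1" else m.n_features))
        )
    vectors = np.hstack(per_source)
    return PairFeatureTable(
        representation=representation,
        pairs=pairs,
        vectors=vectors,
        source_names=tuple(m.source_name for m in matrices),
        source_dims=tuple(m.n_features for m in matrices),
    )


@dataclass(frozen=True)
class VarianceProjection:
    """PCA projection retaining the leading components of a pair table."""

    mean_vector: np.ndarray
    component_matrix: np.ndarray  # shape (n_components, n_original_features)
    retained_variance_fraction: float
    n_components: int
    explained_variance_ratio: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        if not 0 < self.retained_variance_fraction <= 1:
            raise ValueError("retained_variance_fraction must be in (0, 1]")
        if self.n_components != self.component_matrix.shape[0]:
            raise ValueError("n_components inconsistent with component matrix")
        if self.n_components > self.component_matrix.shape[1]:
            raise ValueError("more components than original dimensions")


def fit_variance_projection(
    table: PairFeatureTable | np.ndarray, variance_fraction: float = 0.90
) -> VarianceProjection:
    """Fit the smallest PCA retaining >= ``variance_fraction`` cumulative variance.

    Sign convention: each component's largest-magnitude entry is made
    positive, so the projection is deterministic across runs and platforms.
    """
    from sklearn.decomposition import PCA

    X = table.vectors if isinstance(table, PairFeatureTable) else np.asarray(table, float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows to fit a projection")
    if not 0 < variance_fraction <= 1:
        raise ValueError("variance_fraction must be in (0, 1]")
    if np.allclose(X.var(axis=0), 0.0):
        raise DegenerateInputError("cannot fit a projection on a constant table")
    pca = PCA(svd_solver="full")
    pca.fit(X)
    ratios = pca.explained_variance_ratio_
    cum = np.cumsum(ratios)
    k = int(np.searchsorted(cum, variance_fraction - 1e-12) + 1)
    k = min(k, len(ratios))
    components = pca.components_[:k].copy()
    # deterministic sign: largest-|entry| of each component made positive
    for row in components:
        j = int(np.argmax(np.abs(row)))
        if row[j] < 0:
            row *= -1.0
    return VarianceProjection(
        mean_vector=pca.mean_.copy(),
        component_matrix=components,
        retained_variance_fraction=float(variance_fraction),
        n_components=k,
        explained_variance_ratio=ratios[:k].copy(),
    )


def apply_projection(
    projection: VarianceProjection, vectors: np.ndarray
) -> np.ndarray:
    """Center ``vectors`` and project into component space."""
    X = np.asarray(vectors, dtype=float)
    squeeze = X.ndim == 1
    if squeeze:
        X = X[None, :]
    if X.shape[1] != projection.component_matrix.shape[1]:
        raise LengthMismatchError(
            f"vectors have {X.shape[1]} columns, projection expects "
            f"{projection.component_matrix.shape[1]}"
        )
    scores = (X - projection.mean_vector) @ projection.component_matrix.T
    return scores[0] if squeeze else scores


def project_table(
    table: PairFeatureTable, projection: VarianceProjection
) -> PairFeatureTable:
    """Projected copy of an SFR2 table (representation "SFR2-projected")."""
    return PairFeatureTable(
        representation="SFR2-projected",
        pairs=table.pairs,
        vectors=apply_projection(projection, table.vectors),
        labels=table.labels,
        source_names=table.source_names,
        source_dims=table.source_dims,
    )
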