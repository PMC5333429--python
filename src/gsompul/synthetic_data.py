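"""Synthetic positive-unlabeled benchmarks for the DDI pipeline.

The generator emulates the statistical structure the method assumes:

* drugs fall into latent groups; each source assigns every group a block
  of characteristic features drawn at ``within_group_feature_prob`` while
  the remaining cells fire at ``background_feature_prob`` — so drugs in
  the same group have visibly overlapping binary profiles;
* true interactions follow a rule driven by that structure: ``shared-group``
  (pairs in the same group interact) or ``overlap-threshold`` (mean Jaccard
  across sources above a cutoff), in both cases perturbed by a small label
  flip probability so the task is informative but not trivially separable;
* a fraction ``upp`` (Unlabeled Positive Proportion) of the true
  interactions is masked: those pairs are hidden in the unlabeled pool, as
  in real interaction databases where absence of a record is not evidence
  of non-interaction;
* a subset of the observed positives receives synthetic CYP isoform
  annotations so the annotation stage is exercisable.

All outputs are deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .cyp_annotation import ISOFORMS
from .errors import DegenerateInputError
from .similarity import (
    DrugFeatureMatrix,
    PairKey,
    build_pair_feature_table,
    enumerate_pairs,
)

_DEFAULT_ISOFORM_PROBS = {
    "CYP3A4": 0.5,
    "CYP2D6": 0.3,
    "CYP2C9": 0.2,
    "CYP1A2": 0.15,
    "CYP2C19": 0.1,
}


@dataclass(frozen=True)
class BenchmarkConfig:
    """Generator settings; defaults define the package's standard benchmark."""

    n_drugs: int = 200
    source_dims: tuple[int, ...] = (40, 30, 30, 50)
    n_latent_groups: int = 6
    within_group_feature_prob: float = 0.4
    background_feature_prob: float = 0.08
    interaction_rule: str = "shared-group"  # or "overlap-threshold"
    overlap_threshold: float = 0.3
    interaction_flip_prob: float = 0.02
    upp: float = 0.3
    cyp_annotation_prob: float = 0.3
    cyp_isoform_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_ISOFORM_PROBS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_drugs < 4:
            raise ValueError("need at least 4 drugs")
        if any(d < 1 for d in self.source_dims):
            raise ValueError("source dims must all be >= 1")
        if self.n_latent_groups < 1:
            raise ValueError("need at least one latent group")
        if not self.background_feature_prob < self.within_group_feature_prob:
            raise ValueError("background prob must be below within-group prob")
        if not 0 <= self.upp < 1:
            raise ValueError("upp must be in [0, 1)")
        if self.interaction_rule not in ("shared-group", "overlap-threshold"):
            raise ValueError(f"unknown interaction rule {self.interaction_rule!r}")
        unknown = set(self.cyp_isoform_probs) - ISOFORMS
        if unknown:
            raise ValueError(f"unknown isoforms in config: {sorted(unknown)}")


@dataclass(frozen=True)
class BenchmarkTruth:
    """Ground truth of a generated benchmark (stands in for a curated database)."""

    true_interactions: frozenset[PairKey]
    observed_positives: frozenset[PairKey]
    masked_positives: frozenset[PairKey]
    cyp_annotations: dict[PairKey, frozenset[str]]
    groups: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.observed_positives | self.masked_positives != self.true_interactions:
            raise ValueError("observed and masked must partition the truth")
        if self.observed_positives & self.masked_positives:
            raise ValueError("observed and masked overlap")


def mask_positives(
    true_interactions: frozenset[PairKey] | set[PairKey], upp: float, seed: int
) -> tuple[frozenset[PairKey], frozenset[PairKey]]:
    """Hide round(upp * |true|) uniformly chosen interactions in the unlabeled pool.

    Returns (observed, masked).
    """
    if not 0 <= upp < 1:
        raise ValueError("upp must be in [0, 1)")
    ordered = sorted(true_interactions)
    k = int(round(upp * len(ordered)))
    rng = np.random.default_rng(seed)
    masked_idx = set(rng.choice(len(ordered), size=k, replace=False).tolist()) if k else set()
    masked = frozenset(ordered[i] for i in masked_idx)
    observed = frozenset(p for i, p in enumerate(ordered) if i not in masked_idx)
    return observed, masked


def _draw_cyp_annotations(
    observed: frozenset[PairKey], config: BenchmarkConfig, rng: np.random.Generator
) -> dict[PairKey, frozenset[str]]:
    iso_names = sorted(config.cyp_isoform_probs)
    iso_p = np.array([config.cyp_isoform_probs[n] for n in iso_names])
    out: dict[PairKey, frozenset[str]] = {}
    for pair in sorted(observed):
        if rng.random() >= config.cyp_annotation_prob:
            out[pair] = frozenset()
            continue
        hits = {n for n, p in zip(iso_names, iso_p) if rng.random() < p}
        if not hits:  # annotated pairs carry at least one isoform
            hits = {iso_names[rng.choice(len(iso_names), p=iso_p / iso_p.sum())]}
        out[pair] = frozenset(hits)
    return out


def generate_benchmark(
    config: BenchmarkConfig,
) -> tuple[list[DrugFeatureMatrix], BenchmarkTruth]:
    """Generate binary drug-feature matrices plus PU-masked interaction truth."""
    rng = np.random.default_rng(config.seed)
    n, G = config.n_drugs, config.n_latent_groups
    drug_ids = [f"D{i:04d}" for i in range(n)]
    perm = rng.permutation(n)
    group = np.empty(n, dtype=int)
    for rank, drug in enumerate(perm):
        group[drug] = rank % G

    matrices = []
    for s, dim in enumerate(config.source_dims):
        block = dim // G  # features per group; remainder is pure background
        prob = np.full((n, dim), config.background_feature_prob)
        for g in range(G):
            cols = slice(g * block, (g + 1) * block)
            prob[group == g, cols] = config.within_group_feature_prob
        values = (rng.random((n, dim)) < prob).astype(np.uint8)
        matrices.append(
            DrugFeatureMatrix(
                source_name=f"source{s + 1}",
                drug_ids=tuple(drug_ids),
                feature_ids=tuple(f"S{s + 1}F{j:04d}" for j in range(dim)),
                values=values,
            )
        )

    pairs = enumerate_pairs(drug_ids)
    gid = {d: int(g) for d, g in zip(drug_ids, group)}
    if config.interaction_rule == "shared-group":
        base = np.array([gid[a] == gid[b] for a, b in pairs])
    else:
        sfr1 = build_pair_feature_table(matrices, "SFR1", pairs=pairs)
        base = sfr1.vectors.mean(axis=1) >= config.overlap_threshold
    flips = rng.random(len(pairs)) < config.interaction_flip_prob
    interacting = base ^ flips
    true_interactions = frozenset(p for p, t in zip(pairs, interacting) if t)
    if not true_interactions:
        raise DegenerateInputError(
            "configuration produced zero true interactions; increase group "
            "sizes, the flip probability, or lower the overlap threshold"
        )

    mask_seed = int(rng.integers(0, 2**31))
    observed, masked = mask_positives(true_interactions, config.upp, mask_seed)
    cyp = _draw_cyp_annotations(observed, config, rng)
    truth = BenchmarkTruth(
        true_interactions=true_interactions,
        observed_positives=observed,
        masked_positives=masked,
        cyp_annotations=cyp,
        groups=gid,
    )
    return matrices, truth


def group_signal_summary(
    matrices: list[DrugFeatureMatrix], truth: BenchmarkTruth
) -> dict[str, float]:
    """Mean SFR1 Jaccard (averaged over sources) within vs between groups.

    A usable benchmark must show strictly higher within-group similarity.
    """
    table = build_pair_feature_table(matrices, "SFR1")
    same = []
    diff = []
    for p, v in zip(table.pairs, table.vectors.mean(axis=1)):
        (same if truth.groups[p[0]] == truth.groups[p[1]] else diff).append(v)
    return {
        "within_group_mean_jaccard": float(np.mean(same)),
        "between_group_mean_jaccard": float(np.mean(diff)),
    }
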