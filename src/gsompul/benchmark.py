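"""End-to-end experiments on synthetic PU benchmarks.

Runs the full method (features -> GSOM per representation -> node
profiling -> consensus negatives -> balanced-set SVM ensemble) and the
random-negative baseline on the same generated data, then scores both on
held-back truth: a balanced test set of masked positives (hidden true
interactions the models never saw as positives) and true non-interacting
pairs excluded from every training set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .classification import (
    PREDICTED,
    baseline_random_negatives,
    build_balanced_sets,
    ensemble_predict,
    train_svm,
)
from .evaluation import Metrics, compute_metrics, confusion_from_labels
from .gsom import GSOMConfig, GSOMMap, train_gsom
from .pul_profiling import (
    NegativeSet,
    ambiguous_unlabeled_pairs,
    consensus_negatives,
    infer_negatives,
    profile_nodes,
)
from .similarity import (
    POSITIVE,
    UNLABELED,
    PairFeatureTable,
    build_pair_feature_table,
    fit_variance_projection,
    project_table,
)
from .synthetic_data import BenchmarkConfig, BenchmarkTruth, generate_benchmark


@dataclass(frozen=True)
class ExperimentSettings:
    """Method hyper-parameters used by the benchmark experiments."""

    spread_factor_sfr1: float = 0.1
    spread_factor_sfr2: float = 1e-15
    variance_fraction: float = 0.90
    min_node_size: int = 2
    n_balanced_sets: int = 10
    kernel_degree: int = 2
    c_sfr1: float = 1e-2
    c_sfr2: float = 1e-3
    threshold: float = 0.5
    balanced_set_cap: int | None = 600
    test_positives_cap: int = 500
    gsom: GSOMConfig = field(default_factory=GSOMConfig)


@dataclass
class ExperimentResult:
    seed: int
    n_pairs: int
    n_observed_positives: int
    n_masked_positives: int
    negatives_sfr1: NegativeSet
    negatives_sfr2: NegativeSet
    consensus: NegativeSet
    contamination_consensus: float
    contamination_random_expected: float
    pul_metrics: Metrics
    baseline_metrics: Metrics
    n_test_positives: int


def _masked_fraction(negatives: NegativeSet, truth: BenchmarkTruth) -> float:
    if not negatives.pairs:
        return float("nan")
    return len(negatives.pairs & truth.masked_positives) / len(negatives.pairs)


def build_feature_tables(
    matrices, settings: ExperimentSettings
) -> dict[str, PairFeatureTable]:
    """SFR1 table and variance-projected SFR2 table keyed by representation."""
    sfr1 = build_pair_feature_table(matrices, "SFR1")
    sfr2 = build_pair_feature_table(matrices, "SFR2")
    projection = fit_variance_projection(sfr2, settings.variance_fraction)
    return {"SFR1": sfr1, "SFR2-projected": project_table(sfr2, projection)}


def infer_consensus_negatives(
    tables: Mapping[str, PairFeatureTable],
    labels,
    settings: ExperimentSettings,
    seed: int,
) -> tuple[NegativeSet, dict[str, NegativeSet], dict[str, GSOMMap], dict[str, list]]:
    """GSOM + profiling per representation, intersected into consensus negatives."""
    negative_sets: dict[str, NegativeSet] = {}
    maps: dict[str, GSOMMap] = {}
    profiles: dict[str, list] = {}
    sf = {"SFR1": settings.spread_factor_sfr1, "SFR2-projected": settings.spread_factor_sfr2}
    for i, (rep, table) in enumerate(sorted(tables.items())):
        cfg = replace(settings.gsom, spread_factor=sf[rep], random_seed=(seed * 1000003 + i) % (2**31))
        m = train_gsom(table.vectors, cfg, sample_ids=list(table.pairs))
        prof = profile_nodes(m, labels, min_node_size=settings.min_node_size)
        negative_sets[rep] = infer_negatives(prof, provenance=rep)
        maps[rep] = m
        profiles[rep] = prof
    reps = sorted(negative_sets)
    consensus = consensus_negatives(negative_sets[reps[0]], negative_sets[reps[1]])
    return consensus, negative_sets, maps, profiles


def _train_ensemble(tables, positives, negatives, settings: ExperimentSettings, seed: int):
    sets = build_balanced_sets(
        positives,
        negatives,
        n_sets=settings.n_balanced_sets,
        seed=seed,
        max_per_class=settings.balanced_set_cap,
    )
    c_by_rep = {"SFR1": settings.c_sfr1, "SFR2-projected": settings.c_sfr2}
    models = []
    for rep in sorted(tables):
        for i, ts in enumerate(sets):
            models.append(
                train_svm(
                    ts,
                    tables[rep],
                    kernel_degree=settings.kernel_degree,
                    C=c_by_rep[rep],
                    seed=(seed * 97 + i) % (2**31),
                    training_set_id=i,
                )
            )
    return models


def run_pu_experiment(
    config: BenchmarkConfig,
    settings: ExperimentSettings | None = None,
    classify: bool = True,
) -> ExperimentResult:
    """One full GSOM-PUL vs baseline comparison on a generated benchmark.

    With ``classify=False`` only the negative-inference half runs (for
    contamination studies).
    """
    settings = settings or ExperimentSettings()
    seed = config.seed
    matrices, truth = generate_benchmark(config)
    tables = build_feature_tables(matrices, settings)
    some_table = tables["SFR1"]
    labels = {
        p: (POSITIVE if p in truth.observed_positives else UNLABELED)
        for p in some_table.pairs
    }
    all_pairs = set(some_table.pairs)
    unlabeled = all_pairs - truth.observed_positives

    consensus, per_rep, _maps, _profiles = infer_consensus_negatives(
        tables, labels, settings, seed
    )
    contamination = _masked_fraction(consensus, truth)
    random_expected = len(truth.masked_positives) / len(unlabeled)

    nan_metrics = Metrics(float("nan"), float("nan"), float("nan"))
    result = ExperimentResult(
        seed=seed,
        n_pairs=len(some_table.pairs),
        n_observed_positives=len(truth.observed_positives),
        n_masked_positives=len(truth.masked_positives),
        negatives_sfr1=per_rep["SFR1"],
        negatives_sfr2=per_rep["SFR2-projected"],
        consensus=consensus,
        contamination_consensus=contamination,
        contamination_random_expected=random_expected,
        pul_metrics=nan_metrics,
        baseline_metrics=nan_metrics,
        n_test_positives=0,
    )
    if not classify:
        return result

    rng = np.random.default_rng(seed + 7)
    baseline_negatives = baseline_random_negatives(
        truth.observed_positives, unlabeled, seed=seed + 13
    )

    # held-back test set: masked positives vs true negatives untouched by training
    masked = sorted(truth.masked_positives)
    n_test_pos = min(len(masked), settings.test_positives_cap)
    test_pos = [masked[i] for i in sorted(rng.choice(len(masked), n_test_pos, replace=False))]
    excluded = (
        truth.observed_positives
        | consensus.pairs
        | baseline_negatives.pairs
        | set(test_pos)
    )
    neg_pool = sorted(all_pairs - truth.true_interactions - excluded)
    if len(neg_pool) < n_test_pos:
        raise RuntimeError("not enough clean negative pairs for the test set")
    test_neg = [neg_pool[i] for i in sorted(rng.choice(len(neg_pool), n_test_pos, replace=False))]
    test_pairs = test_pos + test_neg
    y_true = np.array([1] * len(test_pos) + [0] * len(test_neg))

    def score(models) -> Metrics:
        preds = ensemble_predict(models, tables, test_pairs, threshold=settings.threshold)
        by_pair = {p.pair: p for p in preds}
        y_pred = np.array(
            [1 if by_pair[p].decision == PREDICTED else 0 for p in test_pairs]
        )
        return compute_metrics(confusion_from_labels(y_true, y_pred))

    pul_models = _train_ensemble(
        tables, truth.observed_positives, consensus.pairs, settings, seed
    )
    baseline_models = _train_ensemble(
        tables, truth.observed_positives, baseline_negatives.pairs, settings, seed + 1
    )
    result.pul_metrics = score(pul_models)
    result.baseline_metrics = score(baseline_models)
    result.n_test_positives = n_test_pos
    return result


def compare_over_seeds(
    config: BenchmarkConfig,
    seeds,
    settings: ExperimentSettings | None = None,
    classify: bool = True,
) -> list[ExperimentResult]:
    """Repeat the experiment over seeds (all other settings fixed)."""
    return [
        run_pu_experiment(replace(config, seed=int(s)), settings, classify=classify)
        for s in seeds
    ]
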