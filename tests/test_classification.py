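import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gsompul.classification import (
    NOT_PREDICTED,
    PREDICTED,
    BalancedTrainingSet,
    PlattCalibration,
    baseline_random_negatives,
    build_balanced_sets,
    ensemble_predict,
    fit_platt,
    platt_posterior,
    train_one_class,
    train_svm,
)
from gsompul.errors import DegenerateInputError
from gsompul.similarity import PairFeatureTable, PairIndex


def _pairs(n, prefix="p"):
    return [(f"{prefix}{i:03d}a", f"{prefix}{i:03d}b") for i in range(n)]


class TestBalancedSets:
    def test_counts_and_balance(self):
        pos = _pairs(50, "p")
        neg = _pairs(10, "n")
        sets = build_balanced_sets(pos, neg, n_sets=10, seed=0)
        assert len(sets) == 10
        for s in sets:
            assert len(s.positives) == len(s.negatives) == 10
            assert set(s.negatives) == set(neg)  # all negatives kept
            assert set(s.positives) <= set(pos)

    def test_equal_sizes_use_everything(self):
        pos = _pairs(8, "p")
        neg = _pairs(8, "n")
        for s in build_balanced_sets(pos, neg, n_sets=3, seed=1):
            assert set(s.positives) == set(pos)
            assert set(s.negatives) == set(neg)

    def test_deterministic_per_seed_and_distinct_across_sets(self):
        pos = _pairs(100, "p")
        neg = _pairs(20, "n")
        a = build_balanced_sets(pos, neg, n_sets=5, seed=7)
        b = build_balanced_sets(pos, neg, n_sets=5, seed=7)
        assert a == b
        assert len({s.positives for s in a}) > 1  # independent subsamples

    def test_empty_negatives_rejected(self):
        with pytest.raises(DegenerateInputError):
            build_balanced_sets(_pairs(5), [], n_sets=2, seed=0)

    def test_overlapping_classes_rejected(self):
        shared = _pairs(5)
        with pytest.raises(ValueError):
            build_balanced_sets(shared, shared[:2], n_sets=1, seed=0)


class TestPlattPosterior:
    def test_center_value(self):
        assert platt_posterior(0.0, PlattCalibration(0.0, 0.0)) == pytest.approx(0.5)

    def test_hand_computed_value(self):
        # P = 1/(1+exp(-1)) for f=1, A=-1, B=0
        assert platt_posterior(1.0, PlattCalibration(-1.0, 0.0)) == pytest.approx(
            1 / (1 + math.exp(-1)), abs=1e-6
        )

    @pytest.mark.parametrize("f", [-1000.0, 1000.0])
    def test_no_overflow_at_extreme_scores(self, f):
        p = platt_posterior(f, PlattCalibration(-1.0, 0.0))
        assert 0.0 < p < 1.0

    @given(st.floats(-50, 50), st.floats(0.1, 5), st.floats(-5, 5))
    @settings(max_examples=100)
    def test_monotone_in_f(self, f, A, B):
        cal = PlattCalibration(-A, B)  # negative A -> increasing
        assert platt_posterior(f + 1.0, cal) >= platt_posterior(f, cal)

    def test_nonfinite_calibration_rejected(self):
        with pytest.raises(ValueError):
            PlattCalibration(float("nan"), 0.0)


class TestFitPlatt:
    def test_separated_scores_rank_correctly(self):
        f = np.array([-2.0, -1.5, -1.0, 1.0, 1.5, 2.0])
        y = np.array([0, 0, 0, 1, 1, 1])
        cal = fit_platt(f, y)
        p = platt_posterior(f, cal)
        assert (p[y == 1] > 0.5).all()
        assert (p[y == 0] < 0.5).all()

    def test_symmetric_scores_give_half_at_zero(self):
        f = np.concatenate([np.full(50, -1.0), np.full(50, 1.0)])
        y = np.concatenate([np.zeros(50), np.ones(50)]).astype(int)
        cal = fit_platt(f, y)
        assert platt_posterior(0.0, cal) == pytest.approx(0.5, abs=1e-3)

    def test_parameter_recovery_from_known_sigmoid(self):
        """Scores sampled from a known sigmoid recover (A, B) within 5%.

        The per-replicate MLE has standard error ~0.12 at n=1000, so the
        estimator is checked on the mean over replicates.
        """
        A_true, B_true = -2.0, 0.5
        As, Bs = [], []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            f = rng.uniform(-4, 4, size=1000)
            p = 1 / (1 + np.exp(A_true * f + B_true))
            y = (rng.random(1000) < p).astype(int)
            cal = fit_platt(f, y)
            As.append(cal.A)
            Bs.append(cal.B)
        assert np.mean(As) == pytest.approx(A_true, rel=0.05)
        assert np.mean(Bs) == pytest.approx(B_true, abs=0.05)

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateInputError):
            fit_platt(np.array([1.0, 2.0]), np.array([1, 1]))


def _table(pairs, X, representation="SFR1"):
    return PairFeatureTable(
        representation=representation,
        pairs=PairIndex(tuple(pairs)),
        vectors=X,
    )


class TestTrainSvm:
    def test_linearly_separable_toy_set_fits_perfectly(self):
        pos = _pairs(10, "p")
        neg = _pairs(10, "n")
        X = np.vstack([np.random.default_rng(0).normal(3, 0.3, (10, 2)),
                       np.random.default_rng(1).normal(-3, 0.3, (10, 2))])
        table = _table(pos + neg, X)
        model = train_svm(BalancedTrainingSet(tuple(pos), tuple(neg), 0), table, C=1.0)
        pred = model.predict(X)
        assert (pred[:10] == 1).all() and (pred[10:] == 0).all()

    def test_degree_two_kernel_separates_xor(self):
        pos = _pairs(2, "p")
        neg = _pairs(2, "n")
        X = np.array([[1, 1], [-1, -1], [1, -1], [-1, 1]], dtype=float)
        table = _table(pos + neg, X)
        model = train_svm(
            BalancedTrainingSet(tuple(pos), tuple(neg), 0),
            table, kernel_degree=2, C=10.0,
        )
        pred = model.predict(X)
        assert (pred == [1, 1, 0, 0]).all()

    def test_paper_style_config_accepted(self):
        pos = _pairs(10, "p")
        neg = _pairs(10, "n")
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(1, 1, (10, 3)), rng.normal(-1, 1, (10, 3))])
        table = _table(pos + neg, X)
        model = train_svm(
            BalancedTrainingSet(tuple(pos), tuple(neg), 0),
            table, kernel_degree=2, C=1e-2,
        )
        assert model.kernel_degree == 2
        assert model.regularization_C == 1e-2
        assert math.isfinite(model.calibration.A)


class TestEnsemblePredict:
    def _models(self, table, n=3, seed=0):
        pos = list(table.pairs)[:8]
        neg = list(table.pairs)[8:16]
        return [
            train_svm(BalancedTrainingSet(tuple(pos), tuple(neg), i), table, C=1.0, seed=i)
            for i in range(n)
        ]

    def test_identical_models_mean_equals_single(self):
        rng = np.random.default_rng(3)
        pairs = _pairs(20)
        X = np.vstack([rng.normal(2, 0.5, (8, 2)), rng.normal(-2, 0.5, (8, 2)),
                       rng.normal(0, 1, (4, 2))])
        table = _table(pairs, X)
        model = self._models(table, n=1)[0]
        preds = ensemble_predict([model, model], {"SFR1": table}, pairs[16:])
        for p in preds:
            assert p.mean_posterior == pytest.approx(p.per_model_posteriors[0])

    def test_mean_matches_arithmetic_mean_oracle(self):
        rng = np.random.default_rng(4)
        pairs = _pairs(20)
        X = np.vstack([rng.normal(2, 0.5, (8, 2)), rng.normal(-2, 0.5, (8, 2)),
                       rng.normal(0, 1, (4, 2))])
        table = _table(pairs, X)
        models = self._models(table, n=3)
        preds = ensemble_predict(models, {"SFR1": table}, pairs[16:])
        for p in preds:
            assert p.mean_posterior == pytest.approx(
                float(np.mean(p.per_model_posteriors))
            )
            assert 0.0 < p.mean_posterior < 1.0

    def test_decisions_monotone_in_threshold(self):
        rng = np.random.default_rng(5)
        pairs = _pairs(30)
        X = rng.normal(0, 2, (30, 2))
        X[:8] += 3; X[8:16] -= 3
        table = _table(pairs, X)
        models = self._models(table, n=2)
        called = []
        for thr in (0.3, 0.5, 0.7, 0.9):
            preds = ensemble_predict(models, {"SFR1": table}, pairs[16:], threshold=thr)
            called.append({p.pair for p in preds if p.decision == PREDICTED})
        for lo, hi in zip(called[1:], called[:-1]):
            assert lo <= hi  # raising the threshold never adds predictions

    def test_missing_representation_rejected(self):
        rng = np.random.default_rng(6)
        pairs = _pairs(20)
        table = _table(pairs, rng.normal(0, 1, (20, 2)), representation="SFR2")
        models = self._models(_table(pairs, rng.normal(0, 1, (20, 2))), n=1)
        with pytest.raises(KeyError):
            ensemble_predict(models, {"SFR2": table}, pairs[16:])


class TestBaselineAndOneClass:
    def test_baseline_sample_properties(self):
        pos = set(_pairs(10, "p"))
        unl = set(_pairs(40, "u")) | set(list(pos)[:3])
        neg = baseline_random_negatives(pos, unl, seed=0)
        assert len(neg) == len(pos)
        assert not neg.pairs & pos
        assert neg.pairs == baseline_random_negatives(pos, unl, seed=0).pairs
        assert neg.pairs != baseline_random_negatives(pos, unl, seed=1).pairs

    def test_baseline_whole_pool_when_sizes_match(self):
        pos = set(_pairs(5, "p"))
        unl = set(_pairs(5, "u"))
        assert baseline_random_negatives(pos, unl, seed=3).pairs == frozenset(unl)

    def test_baseline_insufficient_pool_rejected(self):
        with pytest.raises(DegenerateInputError):
            baseline_random_negatives(set(_pairs(5)), set(_pairs(2, "u")), seed=0)

    def test_baseline_draws_approximately_uniform(self):
        pool = _pairs(20, "u")
        pos = _pairs(5, "p")
        counts = {p: 0 for p in pool}
        n_draws = 500
        for seed in range(n_draws):
            for p in baseline_random_negatives(set(pos), set(pool), seed=seed).pairs:
                counts[p] += 1
        freq = np.array(list(counts.values()), dtype=float)
        expected = n_draws * len(pos) / len(pool)
        chi2 = float(((freq - expected) ** 2 / expected).sum())
        # chi-square with 19 dof: 0.999 quantile ~ 43.8
        assert chi2 < 43.8

    def test_one_class_svm_inlier_fraction(self):
        rng = np.random.default_rng(7)
        X = rng.normal(0, 1, (500, 2))
        model = train_one_class(X, nu=0.1)
        inside = (model.decision_function(X) >= 0).mean()
        assert inside == pytest.approx(0.9, abs=0.05)
        assert model.decision_function(np.array([[100.0, 100.0]]))[0] < 0

    def test_one_class_degenerate_rejected(self):
        with pytest.raises(DegenerateInputError):
            train_one_class(np.zeros((1, 3)))
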