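"""Balanced-set SVM ensemble with Platt-scaled posteriors.

Known interacting pairs (positives) and inferred negatives are combined
into several balanced training sets; each trains a polynomial-kernel SVM
whose decision values are mapped to posterior probabilities with Platt's
sigmoid

    P(y = 1 | f) = 1 / (1 + exp(A f + B)),

with (A, B) fitted by maximum likelihood on cross-validated decision
values (fitting the sigmoid on in-sample scores is optimistically biased).
A pair's final score is the arithmetic mean of the posteriors across all
models — by default 10 models per representation over two representations,
i.e. 20 posteriors per pair.

Two comparators are provided: the *baseline* that samples negatives
uniformly from the unlabeled pool, and a one-class SVM trained on
positives only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC, OneClassSVM

from .errors import DegenerateInputError
from .pul_profiling import NegativeSet
from .similarity import PairFeatureTable, PairKey

PREDICTED = "predicted_DDI"
NOT_PREDICTED = "not_predicted"


@dataclass(frozen=True)
class BalancedTrainingSet:
    """Equal-size positive/negative pair lists plus the sampling seed."""

    positives: tuple[PairKey, ...]
    negatives: tuple[PairKey, ...]
    seed: int

    def __post_init__(self) -> None:
        if len(self.positives) != len(self.negatives):
            raise ValueError("balanced set requires equal class sizes")
        if set(self.positives) & set(self.negatives):
            raise ValueError("positives and negatives overlap")


def build_balanced_sets(
    positives: Iterable[PairKey],
    negatives: Iterable[PairKey],
    n_sets: int = 10,
    seed: int = 0,
    max_per_class: int | None = None,
) -> list[BalancedTrainingSet]:
    """Construct ``n_sets`` balanced sets by subsampling the larger class.

    In the usual regime (fewer inferred negatives than known positives)
    every set keeps all negatives and draws an equal-size random subsample
    of positives, independently per set.  When negatives outnumber
    positives the roles reverse; ``max_per_class`` optionally caps the
    per-class size.  Sub-seeds are derived deterministically from ``seed``.
    """
    pos = sorted(set(positives))
    neg = sorted(set(negatives))
    if not neg:
        raise DegenerateInputError("cannot build balanced sets without negatives")
    if not pos:
        raise DegenerateInputError("cannot build balanced sets without positives")
    if set(pos) & set(neg):
        raise ValueError("positive and negative pair sets overlap")
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    m = min(len(pos), len(neg))
    if max_per_class is not None:
        m = min(m, max_per_class)
    children = np.random.SeedSequence(seed).spawn(n_sets)
    sets = []
    for child in children:
        rng = np.random.default_rng(child)
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        p = pos if len(pos) == m else [pos[i] for i in sorted(rng.choice(len(pos), m, replace=False))]
        n = neg if len(neg) == m else [neg[i] for i in sorted(rng.choice(len(neg), m, replace=False))]
        sets.append(BalancedTrainingSet(positives=tuple(p), negatives=tuple(n), seed=sub_seed))
    return sets


@dataclass(frozen=True)
class PlattCalibration:
    A: float
    B: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.A) and math.isfinite(self.B)):
            raise ValueError("Platt parameters must be finite")


def platt_posterior(f, calibration: PlattCalibration):
    """P(y=1|f) = 1/(1 + exp(A f + B)), overflow-safe, clipped into (0, 1)."""
    f = np.asarray(f, dtype=float)
    z = calibration.A * f + calibration.B
    # sigma(-z) evaluated stably for large |z|
    out = np.where(z >= 0, np.exp(-np.clip(z, 0, 700)) / (1.0 + np.exp(-np.clip(z, 0, 700))),
                   1.0 / (1.0 + np.exp(np.clip(z, -700, 0))))
    out = np.clip(out, 1e-12, 1.0 - 1e-12)
    return float(out) if out.ndim == 0 else out


def fit_platt(decision_values: np.ndarray, labels: np.ndarray) -> PlattCalibration:
    """Maximum-likelihood sigmoid fit with Platt's target smoothing.

    ``labels`` are binary (1 = positive).  Targets are smoothed to
    (N+ + 1)/(N+ + 2) and 1/(N- + 2), which regularizes the fit when the
    classes are separable.  Deterministic (L-BFGS from a fixed start).
    """
    f = np.asarray(decision_values, dtype=float)
    y = np.asarray(labels).astype(int)
    if f.shape != y.shape or f.ndim != 1:
        raise ValueError("decision_values and labels must be equal-length 1-D")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateInputError("both classes required to fit Platt scaling")
    t = np.where(y == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def nll_grad(theta):
        A, B = theta
        z = A * f + B
        # loss_i = log(1 + e^z) - (1 - t_i) * z  (P = sigma(-z))
        loss = np.logaddexp(0.0, z) - (1.0 - t) * z
        p1 = 1.0 / (1.0 + np.exp(-np.clip(z, -700, 700)))  # sigma(z) = 1 - P
        dz = p1 - (1.0 - t)
        return loss.sum(), np.array([(dz * f).sum(), dz.sum()])

    x0 = np.array([0.0, math.log((n_neg + 1.0) / (n_pos + 1.0))])
    res = minimize(nll_grad, x0, jac=True, method="L-BFGS-B",
                   options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-10})
    A, B = res.x
    return PlattCalibration(A=float(A), B=float(B))


@dataclass
class ClassifierModel:
    """One fitted polynomial-kernel SVM plus its Platt calibration."""

    representation: str
    kernel_degree: int
    regularization_C: float
    svc: SVC
    calibration: PlattCalibration
    training_set_id: int = 0

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        return self.svc.decision_function(np.asarray(X, dtype=float))

    def posterior(self, X: np.ndarray) -> np.ndarray:
        return platt_posterior(self.decision_values(X), self.calibration)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.svc.predict(np.asarray(X, dtype=float)).astype(int)


def _make_svc(kernel_degree: int, C: float) -> SVC:
    if kernel_degree < 1:
        raise ValueError("kernel_degree must be >= 1")
    if C <= 0:
        raise ValueError("C must be positive")
    return SVC(kernel="poly", degree=kernel_degree, C=C, gamma="scale", coef0=1.0)


def train_svm(
    training: BalancedTrainingSet,
    features: PairFeatureTable | Mapping[PairKey, np.ndarray],
    kernel_degree: int = 2,
    C: float = 1e-2,
    calibration_folds: int = 3,
    seed: int = 0,
    training_set_id: int = 0,
) -> ClassifierModel:
    """Fit one SVM on a balanced set and calibrate its posteriors.

    Platt's sigmoid is fitted to out-of-fold decision values from a
    stratified ``calibration_folds``-fold split of the same balanced set;
    the final SVM is then refitted on the full set.
    """
    pairs = list(training.positives) + list(training.negatives)
    y = np.array([1] * len(training.positives) + [0] * len(training.negatives))
    if isinstance(features, PairFeatureTable):
        X = features.matrix_for(pairs)
        representation = features.representation
    else:
        X = np.vstack([np.asarray(features[p], dtype=float) for p in pairs])
        representation = "custom"
    if len(np.unique(y)) < 2:
        raise DegenerateInputError("training set must contain both classes")

    min_class = min(int((y == 1).sum()), int((y == 0).sum()))
    folds = min(calibration_folds, min_class)
    # cross-validated decision values need a couple of examples of each
    # class per training fold to be meaningful
    if folds >= 2 and min_class >= 2 * folds:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed % (2**31))
        dv = np.empty(len(y), dtype=float)
        for tr, te in skf.split(X, y):
            cv_svc = _make_svc(kernel_degree, C)
            cv_svc.fit(X[tr], y[tr])
            dv[te] = cv_svc.decision_function(X[te])
        calibration = fit_platt(dv, y)
    else:  # degenerate tiny sets: calibrate on in-sample scores
        svc0 = _make_svc(kernel_degree, C)
        svc0.fit(X, y)
        calibration = fit_platt(svc0.decision_function(X), y)

    svc = _make_svc(kernel_degree, C)
    svc.fit(X, y)
    return ClassifierModel(
        representation=representation,
        kernel_degree=kernel_degree,
        regularization_C=C,
        svc=svc,
        calibration=calibration,
        training_set_id=training_set_id,
    )


@dataclass(frozen=True)
class EnsemblePrediction:
    pair: PairKey
    per_model_posteriors: tuple[float, ...]
    mean_posterior: float
    decision: str

    def __post_init__(self) -> None:
        if not self.per_model_posteriors:
            raise ValueError("need at least one model posterior")


def ensemble_predict(
    models: Sequence[ClassifierModel],
    features_by_representation: Mapping[str, PairFeatureTable],
    pairs: Iterable[PairKey],
    threshold: float = 0.5,
) -> list[EnsemblePrediction]:
    """Average Platt posteriors over all models and threshold the mean.

    Every model looks up the feature table matching its representation; a
    pair missing from any required table raises ``KeyError``.
    """
    pair_list = sorted(set(pairs))
    if not models:
        raise ValueError("need at least one model")
    posteriors = []
    for model in models:
        table = features_by_representation.get(model.representation)
        if table is None:
            raise KeyError(f"no features for representation {model.representation!r}")
        X = table.matrix_for(pair_list)
        posteriors.append(model.posterior(X))
    P = np.vstack(posteriors)  # (n_models, n_pairs)
    means = P.mean(axis=0)
    return [
        EnsemblePrediction(
            pair=p,
            per_model_posteriors=tuple(float(v) for v in P[:, i]),
            mean_posterior=float(means[i]),
            decision=PREDICTED if means[i] >= threshold else NOT_PREDICTED,
        )
        for i, p in enumerate(pair_list)
    ]


def baseline_random_negatives(
    positives: Iterable[PairKey],
    unlabeled: Iterable[PairKey],
    seed: int = 0,
    n_negatives: int | None = None,
) -> NegativeSet:
    """Baseline negative selection: uniform sample from the unlabeled pool.

    Draws ``n_negatives`` pairs (default: as many as there are positives)
    without replacement from ``unlabeled`` minus ``positives``.
    """
    pos = set(positives)
    pool = sorted(set(unlabeled) - pos)
    k = len(pos) if n_negatives is None else int(n_negatives)
    if k > len(pool):
        raise DegenerateInputError(
            f"unlabeled pool of {len(pool)} cannot supply {k} negatives"
        )
    rng = np.random.default_rng(seed)
    chosen = [pool[i] for i in rng.choice(len(pool), size=k, replace=False)]
    return NegativeSet(pairs=frozenset(chosen), provenance="random-baseline")


def train_one_class(
    positive_features: np.ndarray, nu: float = 0.1, kernel: str = "rbf"
) -> OneClassSVM:
    """One-class SVM comparator trained on positives only."""
    X = np.asarray(positive_features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise DegenerateInputError("one-class SVM needs >= 2 positive rows")
    model = OneClassSVM(nu=nu, kernel=kernel, gamma="scale")
    model.fit(X)
    return model
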