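"""Precision / recall / F1 evaluation with stratified cross-validation.

Conventions for empty denominators: precision (recall) is 0 when no pairs
were predicted positive (no positives exist), and F1 is 0 when precision
and recall are both 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class Metrics:
    precision: float
    recall: float
    f1: float


def confusion_from_labels(y_true, y_pred) -> ConfusionCounts:
    """Count TP/FP/FN/TN from binary truth and prediction vectors."""
    yt = np.asarray(y_true).astype(int)
    yp = np.asarray(y_pred).astype(int)
    if yt.shape != yp.shape:
        raise ValueError("y_true and y_pred must have equal length")
    return ConfusionCounts(
        tp=int(((yt == 1) & (yp == 1)).sum()),
        fp=int(((yt == 0) & (yp == 1)).sum()),
        fn=int(((yt == 1) & (yp == 0)).sum()),
        tn=int(((yt == 0) & (yp == 0)).sum()),
    )


def compute_metrics(counts: ConfusionCounts) -> Metrics:
    """Precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = 2PR/(P+R)."""
    p = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    r = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r > 0 else 0.0
    return Metrics(precision=p, recall=r, f1=f1)


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 if both are 0)."""
    if precision + recall <= 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def kfold_cv(
    X: np.ndarray,
    y: Sequence[int],
    k: int,
    trainer: Callable[[np.ndarray, np.ndarray], object],
    seed: int = 0,
) -> tuple[Metrics, list[Metrics]]:
    """Mean metrics over ``k`` stratified folds.

    ``trainer(X_train, y_train)`` must return an object with a
    ``predict(X) -> binary labels`` method.  Returns (mean, per-fold).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError("every fold must contain both classes; reduce k")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**31))
    fold_metrics = []
    for tr, te in skf.split(X, y):
        model = trainer(X[tr], y[tr])
        pred = np.asarray(model.predict(X[te])).astype(int)
        fold_metrics.append(compute_metrics(confusion_from_labels(y[te], pred)))
    mean = Metrics(
        precision=float(np.mean([m.precision for m in fold_metrics])),
        recall=float(np.mean([m.recall for m in fold_metrics])),
        f1=float(np.mean([m.f1 for m in fold_metrics])),
    )
    return mean, fold_metrics


def holdout_split(
    items: Sequence, y: Sequence[int], train_fraction: float, seed: int = 0
) -> tuple[list, list]:
    """Stratified train/test split of ``items`` by binary labels ``y``."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    y = np.asarray(y).astype(int)
    if len(items) != len(y):
        raise ValueError("items and labels must have equal length")
    idx = np.arange(len(y))
    try:
        tr, te = train_test_split(
            idx,
            train_size=train_fraction,
            stratify=y,
            random_state=seed % (2**31),
            shuffle=True,
        )
    except ValueError as exc:
        raise ValueError(f"split leaves a class empty: {exc}") from exc
    items = list(items)
    return [items[i] for i in sorted(tr)], [items[i] for i in sorted(te)]
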