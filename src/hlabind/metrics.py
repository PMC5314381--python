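"""Binary-classification evaluation: confusion counts, SN/SP/ACC/MCC, folds.

The positive class is high affinity throughout. Any metric whose denominator
vanishes (a degenerate predictor or a single-class fold pool) is reported as
0 by convention, so all-negative predictors on the imbalanced data yield
SN = 0, SP = 1, ACC = 1 - positive rate, MCC = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.tn + other.tn,
            self.fp + other.fp, self.fn + other.fn,
        )


def confusion(y_true, y_pred, positive=1) -> ConfusionMatrix:
    """Tally TP/TN/FP/FN with ``positive`` as the positive-class label."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    t = y_true == positive
    p = y_pred == positive
    return ConfusionMatrix(
        tp=int(np.sum(t & p)),
        tn=int(np.sum(~t & ~p)),
        fp=int(np.sum(~t & p)),
        fn=int(np.sum(t & ~p)),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den else 0.0


def sn(cm: ConfusionMatrix) -> float:
    """Sensitivity (recall of the positive class): TP / (TP + FN)."""
    _check(cm)
    return _ratio(cm.tp, cm.tp + cm.fn)


def sp(cm: ConfusionMatrix) -> float:
    """Specificity: TN / (TN + FP)."""
    _check(cm)
    return _ratio(cm.tn, cm.tn + cm.fp)


def acc(cm: ConfusionMatrix) -> float:
    """Accuracy: (TP + TN) / total."""
    _check(cm)
    return (cm.tp + cm.tn) / cm.total


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient in [-1, 1]; 0 on zero denominator."""
    _check(cm)
    den = (
        (cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    )
    if den == 0:
        return 0.0
    return (cm.tp * cm.tn - cm.fp * cm.fn) / math.sqrt(den)


def _check(cm: ConfusionMatrix) -> None:
    if cm.total == 0:
        raise ValueError("empty confusion matrix")


def stratified_folds(y, k: int = 10, seed: int = 0) -> np.ndarray:
    """Deterministic stratified fold assignment.

    Indices of each class are shuffled with ``seed`` and dealt round-robin
    across ``k`` folds, so per-class counts across folds differ by at most
    one. Raises if any class has fewer than ``k`` members, since such a
    split would leave folds without both classes.

    Returns
    -------
    ndarray of int
        Fold id in ``[0, k)`` for every sample.
    """
    y = np.asarray(y)
    if k < 2:
        raise ValueError(f"need at least 2 folds, got {k}")
    rng = np.random.default_rng(seed)
    assignment = np.empty(len(y), dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if len(idx) < k:
            raise ValueError(
                f"class {cls!r} has only {len(idx)} members, fewer than k={k} "
                f"folds; use a smaller k"
            )
        idx = rng.permutation(idx)
        assignment[idx] = np.arange(len(idx)) % k
    return assignment
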