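"""Binary classification metrics for lesion recognition.

Malignant is the positive class (label 1) throughout, so TP counts
correctly flagged melanomas and TN correctly cleared benign lesions.
Metrics on degenerate confusion matrices raise
:class:`UndefinedMetricError` rather than silently returning 0 or 1;
the single conventional exception is F1 = 0 when precision and recall
are both zero.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "UndefinedMetricError",
    "ConfusionMatrix",
    "MetricsReport",
    "confusion_from_predictions",
    "accuracy",
    "sensitivity",
    "recall",
    "specificity",
    "precision",
    "f1",
    "roc_auc",
    "roc_curve_points",
    "kfold_indices",
    "as_percent",
    "metrics_report",
]


class UndefinedMetricError(ValueError):
    """Raised when a metric's denominator is zero."""


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    def render(self) -> str:
        """Plain-text 2x2 table, predicted columns x true rows."""
        return (
            "              pred benign  pred malignant\n"
            f"true benign   {self.tn:11d}  {self.fp:14d}\n"
            f"true malignant{self.fn:11d}  {self.tp:14d}"
        )


def confusion_from_predictions(y_true, y_pred) -> ConfusionMatrix:
    """Count the four confusion cells from binary label vectors."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} must contain only 0/1 labels")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn)


def accuracy(cm: ConfusionMatrix) -> float:
    """(TP + TN) / (TP + FP + TN + FN)."""
    if cm.total == 0:
        raise UndefinedMetricError("accuracy undefined on an empty confusion matrix")
    return (cm.tp + cm.tn) / cm.total


def sensitivity(cm: ConfusionMatrix) -> float:
    """TP / (TP + FN): fraction of true melanomas detected."""
    if cm.tp + cm.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no positive instances")
    return cm.tp / (cm.tp + cm.fn)


recall = sensitivity


def specificity(cm: ConfusionMatrix) -> float:
    """TN / (TN + FP): fraction of benign lesions correctly cleared."""
    if cm.tn + cm.fp == 0:
        raise UndefinedMetricError("specificity undefined: no negative instances")
    return cm.tn / (cm.tn + cm.fp)


def precision(cm: ConfusionMatrix) -> float:
    """TP / (TP + FP): correctness of malignant calls."""
    if cm.tp + cm.fp == 0:
        raise UndefinedMetricError("precision undefined: no positive predictions")
    return cm.tp / (cm.tp + cm.fp)


def f1(cm: ConfusionMatrix) -> float:
    """Harmonic mean of precision and recall, 2PR/(P+R); 0 when TP = 0."""
    if cm.tp == 0:
        if cm.fp == 0 and cm.fn == 0:
            raise UndefinedMetricError("f1 undefined: no positives anywhere")
        warnings.warn("precision and recall are both zero; defining f1 = 0")
        return 0.0
    p = precision(cm)
    r = sensitivity(cm)
    return 2.0 * p * r / (p + r)


def roc_auc(scores, y_true) -> float:
    """Rank-based AUC: the probability that a random positive outscores a
    random negative, with ties counted half (the Mann-Whitney statistic
    divided by n_pos * n_neg)."""
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true)
    if scores.shape != y_true.shape:
        raise ValueError("scores and y_true must have equal length")
    n_pos = int(np.sum(y_true == 1))
    n_neg = int(np.sum(y_true == 0))
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC undefined: only one class present")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    u = ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_curve_points(scores, y_true) -> "np.ndarray":
    """ROC curve as an array of (fpr, tpr, threshold) rows, one per
    distinct score threshold, descending."""
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true)
    n_pos = np.sum(y_true == 1)
    n_neg = np.sum(y_true == 0)
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("ROC undefined: only one class present")
    order = np.argsort(-scores, kind="stable")
    rows = [(0.0, 0.0, np.inf)]
    tp = fp = 0
    sorted_scores = scores[order]
    sorted_y = y_true[order]
    for i in range(len(order)):
        if sorted_y[i] == 1:
            tp += 1
        else:
            fp += 1
        if i + 1 == len(order) or sorted_scores[i + 1] != sorted_scores[i]:
            rows.append((fp / n_neg, tp / n_pos, float(sorted_scores[i])))
    return np.asarray(rows)


def kfold_indices(n: int, k: int, strata, seed: int):
    """Stratified k-fold split of range(n); returns [(train_idx, test_idx)].

    Every stratum must have at least k members so each fold sees each
    stratum.
    """
    strata = np.asarray(strata)
    if k < 2:
        raise ValueError("k must be >= 2")
    values, counts = np.unique(strata, return_counts=True)
    small = values[counts < k]
    if small.size:
        raise ValueError(
            f"stratum {small[0]!r} has fewer than k={k} members; cannot stratify"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**31))
    return list(skf.split(np.zeros(n), strata))


def as_percent(fraction: float, decimals: int = 2) -> float:
    """Report a fraction as a percentage, half-up at ``decimals`` places."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(fraction * 100.0)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MetricsReport:
    """The six headline metrics as fractions in [0, 1]."""

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    auc: float

    def as_percent_dict(self) -> dict[str, float]:
        return {k: as_percent(v) for k, v in asdict(self).items()}

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def metrics_report(y_true, y_pred, scores) -> MetricsReport:
    """Compute the full report from labels, hard predictions and scores."""
    cm = confusion_from_predictions(y_true, y_pred)
    return MetricsReport(
        accuracy=accuracy(cm),
        sensitivity=sensitivity(cm),
        specificity=specificity(cm),
        precision=precision(cm),
        f1=f1(cm),
        auc=roc_auc(scores, y_true),
    )
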