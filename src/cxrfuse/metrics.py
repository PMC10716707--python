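"""Binary-classification metric suite used throughout the treatment-benefit
experiments.

The positive class is "will benefit from corticosteroid treatment".  All
ratio metrics come straight from the confusion counts:

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    precision   = TP / (TP + FP)
    recall      = sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    F1          = 2 * precision * recall / (precision + recall)
    balanced accuracy = (sensitivity + specificity) / 2

Ratios with a zero denominator are reported as NaN (an explicit
"undefined" marker), never silently as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from sklearn.metrics import roc_auc_score


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float
    balanced_accuracy: float
    roc_auc: float = math.nan

    def rounded(self, ndigits: int = 4) -> dict[str, float]:
        """Report-style dict, rounded to 4 decimals by default."""
        return {k: round(v, ndigits) for k, v in asdict(self).items()}


def _as_binary(y, name: str) -> np.ndarray:
    arr = np.asarray(y)
    vals = np.unique(arr)
    if not np.isin(vals, [0, 1]).all():
        raise ValueError(f"{name} must be binary 0/1, found values {vals}")
    return arr.astype(int)


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Exact confusion counts; positive class = benefit."""
    t = _as_binary(y_true, "y_true")
    p = _as_binary(y_pred, "y_pred")
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {p.shape}")
    return ConfusionCounts(
        tp=int(((t == 1) & (p == 1)).sum()),
        tn=int(((t == 0) & (p == 0)).sum()),
        fp=int(((t == 0) & (p == 1)).sum()),
        fn=int(((t == 1) & (p == 0)).sum()),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (NaN if both are zero)."""
    for v, name in ((precision, "precision"), (recall, "recall")):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    if precision + recall == 0:
        return math.nan
    return 2.0 * precision * recall / (precision + recall)


def metrics_from_counts(c: ConfusionCounts) -> MetricsReport:
    """Apply the metric formulas exactly to a set of confusion counts."""
    if c.total == 0:
        raise ValueError("all confusion counts are zero")
    precision = _ratio(c.tp, c.tp + c.fp)
    recall = _ratio(c.tp, c.tp + c.fn)
    specificity = _ratio(c.tn, c.tn + c.fp)
    if math.isnan(precision) or math.isnan(recall) or precision + recall == 0:
        f1 = math.nan
    else:
        f1 = f1_from_precision_recall(precision, recall)
    balanced = (recall + specificity) / 2.0
    return MetricsReport(
        accuracy=_ratio(c.tp + c.tn, c.total),
        precision=precision,
        recall=recall,
        specificity=specificity,
        f1=f1,
        balanced_accuracy=balanced,
    )


def roc_auc(scores, y_true) -> float:
    """Area under the ROC curve: the probability that a random positive
    outranks a random negative, ties counted half."""
    t = _as_binary(y_true, "y_true")
    s = np.asarray(scores, dtype=float)
    if t.shape != s.shape:
        raise ValueError("scores and labels must share length")
    if len(np.unique(t)) < 2:
        raise ValueError("ROC-AUC needs both classes present")
    return float(roc_auc_score(t, s))


def evaluate_predictions(y_true, y_pred, scores=None) -> MetricsReport:
    """Full report from hard predictions plus optional continuous scores."""
    rep = metrics_from_counts(confusion(y_true, y_pred))
    if scores is not None:
        rep = MetricsReport(**{**asdict(rep), "roc_auc": roc_auc(scores, y_true)})
    return rep
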