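"""Binary classifier evaluation: confusion counts, the standard scalar
metrics, and ROC/AUC.

Positive class is nuclear throughout. Accuracy, sensitivity (recall of the
nuclear class), specificity, F1 (harmonic mean of precision and recall)
and the Matthews correlation coefficient are computed directly from the
confusion counts. Undefined ratios are reported as NaN except MCC, which
follows the common convention of 0 when any denominator factor vanishes.

The ROC curve is swept over all score cutoffs; AUC is the trapezoidal
area, which with half-credit tie handling equals the Mann–Whitney
concordance probability P(score_pos > score_neg) + 0.5 P(tie).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = ["ConfusionCounts", "MetricsReport", "confusion", "metrics", "roc_auc",
           "evaluate_predictions"]

POSITIVE = "nuclear"
NEGATIVE = "cytosolic"


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    mcc: float
    auc: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def confusion(
    predicted: Sequence[str], truth: Sequence[str], positive: str = POSITIVE
) -> ConfusionCounts:
    """Tally TP/TN/FP/FN over paired label vectors."""
    pred = np.asarray(predicted)
    true = np.asarray(truth)
    if pred.shape != true.shape:
        raise ValidationError(
            f"length mismatch: {pred.shape[0]} predictions vs {true.shape[0]} truths"
        )
    known = {POSITIVE, NEGATIVE}
    unknown = (set(np.unique(pred)) | set(np.unique(true))) - known
    if unknown:
        raise ValidationError(f"unknown labels {sorted(unknown)}")
    p = pred == positive
    t = true == positive
    return ConfusionCounts(
        tp=int(np.sum(p & t)),
        tn=int(np.sum(~p & ~t)),
        fp=int(np.sum(p & ~t)),
        fn=int(np.sum(~p & t)),
    )


def metrics(counts: ConfusionCounts) -> MetricsReport:
    """Scalar metrics from confusion counts.

    accuracy    = (TP + TN) / total
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    F1          = harmonic mean of precision TP/(TP+FP) and sensitivity
    MCC         = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    if counts.total < 1:
        raise ValidationError("metrics require at least one item")

    def ratio(num: float, den: float) -> float:
        return num / den if den > 0 else float("nan")

    accuracy = (tp + tn) / counts.total
    sensitivity = ratio(tp, tp + fn)
    specificity = ratio(tn, tn + fp)
    precision = ratio(tp, tp + fp)
    if math.isnan(precision) or math.isnan(sensitivity) or precision + sensitivity == 0:
        f1 = float("nan") if (math.isnan(precision) or math.isnan(sensitivity)) else 0.0
    else:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom > 0 else 0.0
    return MetricsReport(
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        precision=precision,
        f1=f1,
        mcc=mcc,
    )


def roc_auc(
    scores: Sequence[float], truth: Sequence[str]
) -> tuple[list[tuple[float, float, float]], float]:
    """ROC points (FPR, TPR, cutoff) and trapezoidal AUC.

    Scores are P(nuclear); the point recorded for a cutoff counts items
    with score >= cutoff as positive. The curve starts at (0, 0) (cutoff
    +inf) and ends at
    (1, 1); tied scores collapse to one operating point, giving half
    credit to ties in the area.
    """
    s = np.asarray(scores, dtype=np.float64)
    t = np.asarray(truth)
    if s.shape != t.shape:
        raise ValidationError("scores and truth length mismatch")
    pos = t == POSITIVE
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("ROC requires at least one positive and one negative")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    pos_sorted = pos[order]
    # collapse tied scores into single operating points
    distinct = np.nonzero(np.diff(s_sorted))[0]
    boundaries = np.concatenate([distinct, [s.size - 1]])
    tp_cum = np.cumsum(pos_sorted)[boundaries]
    fp_cum = np.cumsum(~pos_sorted)[boundaries]
    tpr = np.concatenate([[0.0], tp_cum / n_pos])
    fpr = np.concatenate([[0.0], fp_cum / n_neg])
    cutoffs = np.concatenate([[np.inf], s_sorted[boundaries]])
    auc = float(np.trapezoid(tpr, fpr))
    points = list(zip(fpr.tolist(), tpr.tolist(), cutoffs.tolist()))
    return points, auc


def evaluate_predictions(
    proba: pd.DataFrame, truth: Sequence[str], cutoff: float = 0.5
) -> MetricsReport:
    """Full report from predicted probabilities and true labels."""
    from .model import classify  # deferred: metrics has no other model dep

    predicted = classify(proba, cutoff=cutoff)
    report = metrics(confusion(predicted.to_numpy(), truth))
    _, auc = roc_auc(proba["P_nuclear"].to_numpy(), truth)
    return MetricsReport(**{**report.to_dict(), "auc": auc})
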