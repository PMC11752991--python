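"""Binary-classification metrics: PRE, SEN, SPE, ACC, F1, ROC-AUC, PR-AUC.

Threshold metrics are derived from the raw confusion counts.  Degenerate
predictors make precision (and hence F1) undefined — an all-negative
predictor has no predicted positives — and those states are kept as NaN and
rendered as "-", never coerced to zero.  Ranking metrics use the trapezoidal
ROC area and the average-precision (step-curve) PR area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = ["MetricsReport", "confusion_metrics", "roc_auc", "pr_auc",
           "full_report"]

METRIC_COLUMNS = ("PRE", "SEN", "SPE", "ACC", "F1", "ROC_AUC", "PR_AUC")


@dataclass
class MetricsReport:
    """Confusion counts plus the seven derived metrics (NaN = undefined)."""

    TP: int
    FP: int
    TN: int
    FN: int
    PRE: float
    SEN: float
    SPE: float
    ACC: float
    F1: float
    ROC_AUC: float = math.nan
    PR_AUC: float = math.nan

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    def to_dict(self) -> dict:
        return {"TP": self.TP, "FP": self.FP, "TN": self.TN, "FN": self.FN,
                **{k: getattr(self, k) for k in METRIC_COLUMNS}}

    def formatted(self) -> dict:
        """Four-decimal strings with "-" for undefined entries."""
        out = {}
        for k in METRIC_COLUMNS:
            v = getattr(self, k)
            out[k] = "-" if (v is None or math.isnan(v)) else f"{v:.4f}"
        return out


def _validate_binary(labels, other, other_name) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(labels)
    z = np.asarray(other)
    if y.size == 0:
        raise ValueError("empty input")
    if y.shape != z.shape:
        raise ValueError(f"labels and {other_name} have different lengths "
                         f"({y.size} vs {z.size})")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    return y.astype(int), z


def confusion_metrics(labels, predicted_labels) -> MetricsReport:
    """Threshold metrics from true and predicted binary labels."""
    y, p = _validate_binary(labels, predicted_labels, "predictions")
    if not np.isin(p, (0, 1)).all():
        raise ValueError("predicted labels must be binary 0/1")
    p = p.astype(int)
    tp = int(np.sum((y == 1) & (p == 1)))
    fp = int(np.sum((y == 0) & (p == 1)))
    tn = int(np.sum((y == 0) & (p == 0)))
    fn = int(np.sum((y == 1) & (p == 0)))
    pre = tp / (tp + fp) if tp + fp > 0 else math.nan
    sen = tp / (tp + fn) if tp + fn > 0 else math.nan
    spe = tn / (tn + fp) if tn + fp > 0 else math.nan
    acc = (tp + tn) / (tp + fp + tn + fn)
    if math.isnan(pre) or math.isnan(sen) or pre + sen == 0:
        f1 = math.nan
    else:
        f1 = 2.0 * pre * sen / (pre + sen)
    return MetricsReport(TP=tp, FP=fp, TN=tn, FN=fn,
                         PRE=pre, SEN=sen, SPE=spe, ACC=acc, F1=f1)


def roc_auc(labels, scores) -> float:
    """Trapezoidal area under the ROC curve (= normalized Mann-Whitney U)."""
    y, s = _validate_binary(labels, scores, "scores")
    if y.min() == y.max():
        raise ValueError("both classes must be present for ROC-AUC")
    return float(roc_auc_score(y, s.astype(float)))


def pr_auc(labels, scores) -> float:
    """Average-precision area under the precision-recall step curve."""
    y, s = _validate_binary(labels, scores, "scores")
    if y.sum() == 0:
        raise ValueError("at least one positive is required for PR-AUC")
    return float(average_precision_score(y, s.astype(float)))


def full_report(labels, scores, threshold: float = 0.5) -> MetricsReport:
    """Threshold + ranking metrics from scores; label = 1 when score >= threshold."""
    y, s = _validate_binary(labels, scores, "scores")
    rep = confusion_metrics(y, (s.astype(float) >= threshold).astype(int))
    if y.min() != y.max():
        rep.ROC_AUC = roc_auc(y, s)
    if y.sum() > 0:
        rep.PR_AUC = pr_auc(y, s)
    return rep
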