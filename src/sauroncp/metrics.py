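"""Confusion-matrix and association metrics used in the evaluation.

Undefined quantities (zero denominators, constant vectors) are reported as
NaN, never silently as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import matthews_corrcoef

__all__ = ["ConfusionSummary", "confusion_metrics", "association_metrics"]


@dataclass
class ConfusionSummary:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float   # TP / (TP + FN)
    miss_rate: float     # FN / (TP + FN)
    specificity: float   # TN / (TN + FP)
    fall_out: float      # FP / (TN + FP)


def _rate(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def confusion_metrics(truth, predicted, positive_label=1) -> ConfusionSummary:
    """Binary confusion counts and rates with ``positive_label`` as positive."""
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape:
        raise ValueError("truth and prediction vectors must have equal length")
    pos_t = truth == positive_label
    pos_p = predicted == positive_label
    tp = int(np.sum(pos_t & pos_p))
    fn = int(np.sum(pos_t & ~pos_p))
    tn = int(np.sum(~pos_t & ~pos_p))
    fp = int(np.sum(~pos_t & pos_p))
    return ConfusionSummary(tp, fp, tn, fn,
                            sensitivity=_rate(tp, tp + fn),
                            miss_rate=_rate(fn, tp + fn),
                            specificity=_rate(tn, tn + fp),
                            fall_out=_rate(fp, tn + fp))


def association_metrics(y_true, y_pred, labels_true=None, labels_pred=None) -> dict:
    """MSE / Pearson / Spearman on continuous values plus (generalized,
    multi-class capable) MCC on labels when labels are supplied."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch between truths and predictions")
    out = {"MSE": float(np.mean((y_true - y_pred) ** 2))}
    if np.ptp(y_true) == 0 or np.ptp(y_pred) == 0:
        out["PCC"] = float("nan")
        out["SCC"] = float("nan")
    else:
        out["PCC"] = float(stats.pearsonr(y_true, y_pred).statistic)
        out["SCC"] = float(stats.spearmanr(y_true, y_pred).statistic)
    if labels_true is not None and labels_pred is not None:
        lt = np.asarray(labels_true)
        lp = np.asarray(labels_pred)
        if lt.shape != lp.shape:
            raise ValueError("length mismatch between label vectors")
        if len(np.unique(lt)) < 2 or len(np.unique(lp)) < 2:
            out["MCC"] = float("nan")
        else:
            out["MCC"] = float(matthews_corrcoef(lt, lp))
    return out
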