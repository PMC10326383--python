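"""Classification metrics: confusion counts, ACC/SEN/SPE, ROC and AUC.

The positive class is the abnormal (AD) group, label 1; sensitivity is
the true-positive rate on that class and specificity the true-negative
rate on healthy controls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn import metrics as _skm


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.tn + self.fp + self.fn < 1:
            raise ValueError("confusion counts must describe at least one case")


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


def confusion(labels, predictions) -> ConfusionCounts:
    y = np.asarray(labels).astype(int)
    p = np.asarray(predictions).astype(int)
    if y.shape != p.shape:
        raise ValueError("labels and predictions differ in length")
    if not (np.isin(y, (0, 1)).all() and np.isin(p, (0, 1)).all()):
        raise ValueError("labels and predictions must be binary")
    return ConfusionCounts(
        tp=int(((y == 1) & (p == 1)).sum()),
        tn=int(((y == 0) & (p == 0)).sum()),
        fp=int(((y == 0) & (p == 1)).sum()),
        fn=int(((y == 1) & (p == 0)).sum()),
    )


def acc_sen_spe(c: ConfusionCounts) -> tuple[float, float, float]:
    """Accuracy, sensitivity (TP rate) and specificity (TN rate)."""
    if c.tp + c.fn == 0:
        raise ValueError("SEN undefined: no positive cases (TP + FN = 0)")
    if c.tn + c.fp == 0:
        raise ValueError("SPE undefined: no negative cases (TN + FP = 0)")
    acc = (c.tp + c.tn) / (c.tp + c.tn + c.fp + c.fn)
    sen = c.tp / (c.tp + c.fn)
    spe = c.tn / (c.fp + c.tn)
    return acc, sen, spe


def roc_curve(scores, labels) -> RocCurve:
    """ROC sweep over all distinct score thresholds (ties grouped)."""
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("scores and labels differ in length")
    if len(set(y.tolist())) < 2:
        raise ValueError("ROC needs at least one positive and one negative")
    fpr, tpr, thr = _skm.roc_curve(y, s, pos_label=1)
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr)


def auc(curve: RocCurve) -> float:
    """Area under the ROC curve by trapezoidal integration."""
    return float(np.trapezoid(curve.tpr, curve.fpr))


def auc_from_scores(scores, labels) -> float:
    return auc(roc_curve(scores, labels))
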