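"""Segmentation and classification metrics.

Mask agreement: Jaccard index |A∩B| / |A∪B| (1 when both masks are empty)
with its complement distance, and the RMS mask error
sqrt(fraction of disagreeing pixels).  Classification: one-vs-rest confusion
counts; sensitivity TP/(TP+FN), specificity TN/(TN+FP), precision
TP/(TP+FP), accuracy (TP+TN)/total and fall-out FP/(FP+TN) = 1-specificity;
and a threshold-swept ROC whose trapezoid AUC equals the normalized
Mann-Whitney rank statistic (ties counted one half).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class ROCCurve:
    fall_out: np.ndarray     # non-decreasing, starts 0 ends 1
    sensitivity: np.ndarray  # non-decreasing, starts 0 ends 1
    thresholds: np.ndarray
    auc: float


def jaccard(mask_a, mask_b):
    """(index, distance) of two same-shape {0,1} masks."""
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    union = (a | b).sum()
    if union == 0:
        return 1.0, 0.0
    index = float((a & b).sum() / union)
    return index, 1.0 - index


def rms_error(mask_a, mask_b) -> float:
    """sqrt(mean squared mask disagreement) = sqrt(disagreeing fraction)."""
    a = np.asarray(mask_a).astype(float)
    b = np.asarray(mask_b).astype(float)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    return float(np.sqrt(((a - b) ** 2).mean()))


def confusion(pred_labels, true_labels, positive_class) -> ConfusionCounts:
    """One-vs-rest confusion counts for a chosen positive class."""
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if pred.size == 0:
        raise ValueError("empty inputs")
    if pred.shape != true.shape:
        raise ValueError("prediction/truth length mismatch")
    p = pred == positive_class
    t = true == positive_class
    return ConfusionCounts(
        TP=int((p & t).sum()), TN=int((~p & ~t).sum()),
        FP=int((p & ~t).sum()), FN=int((~p & t).sum()),
    )


def pixel_confusion(pred_mask, true_mask) -> ConfusionCounts:
    """Confusion counts treating each pixel as one binary decision."""
    return confusion(
        np.asarray(pred_mask).astype(bool).ravel(),
        np.asarray(true_mask).astype(bool).ravel(),
        True,
    )


def _rate(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name}: 0/0 undefined, reporting NaN")
        return float("nan")
    return num / den


def metrics(counts: ConfusionCounts) -> dict:
    """Sensitivity, specificity, precision, accuracy and fall-out.

    Any 0/0 rate is reported as NaN with a warning, never an exception.
    """
    return {
        "sensitivity": _rate(counts.TP, counts.TP + counts.FN, "sensitivity"),
        "specificity": _rate(counts.TN, counts.TN + counts.FP, "specificity"),
        "precision": _rate(counts.TP, counts.TP + counts.FP, "precision"),
        "accuracy": _rate(counts.TP + counts.TN, counts.total, "accuracy"),
        "fall_out": _rate(counts.FP, counts.FP + counts.TN, "fall_out"),
    }


def roc(scores, true_labels, positive_class) -> ROCCurve:
    """ROC curve over thresholds at every unique score (plus ±inf endpoints).

    A sample is predicted positive when score >= threshold.  The trapezoid
    AUC equals P(score_pos > score_neg) + 0.5 P(tie) (Mann-Whitney).
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(true_labels) == positive_class
    n_pos, n_neg = int(t.sum()), int((~t).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative")
    thresholds = np.concatenate(([np.inf], np.unique(s)[::-1], [-np.inf]))
    tpr = np.empty(thresholds.size)
    fpr = np.empty(thresholds.size)
    for i, thr in enumerate(thresholds):
        pred = s >= thr
        tpr[i] = (pred & t).sum() / n_pos
        fpr[i] = (pred & ~t).sum() / n_neg
    order = np.lexsort((tpr, fpr))
    fpr, tpr, thresholds = fpr[order], tpr[order], thresholds[order]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fall_out=fpr, sensitivity=tpr, thresholds=thresholds, auc=auc)


__all__ = [
    "ConfusionCounts", "ROCCurve",
    "jaccard", "rms_error", "confusion", "pixel_confusion", "metrics", "roc",
]
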