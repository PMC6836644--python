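"""Confusion-matrix construction and the two model-selection objectives.

The Matthews correlation coefficient (MCC) and the positive predictive value
(PPV) are the only measures the selection logic consumes; accuracy and raw
error counts are derived summaries used in reports.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from mcscreen.core_data import ACTIVE, INACTIVE, UNKNOWN

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FP/TN/FN counts with ``Active`` as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def as_dict(self) -> dict[str, int]:
        return {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn}


def confusion_matrix(
    true_labels: Sequence[str], pred_labels: Sequence[str]
) -> ConfusionMatrix:
    """Count TP/FP/TN/FN over paired label vectors.

    Both vectors must contain only ``Active``/``Inactive``; an ``Unknown``
    label anywhere is an error (the caller must hold ground truth).
    """
    true_labels = list(true_labels)
    pred_labels = list(pred_labels)
    if len(true_labels) != len(pred_labels):
        raise ValueError(
            f"length mismatch: {len(true_labels)} true vs {len(pred_labels)} predicted"
        )
    tp = fp = tn = fn = 0
    for t, p in zip(true_labels, pred_labels):
        if t not in (ACTIVE, INACTIVE) or p not in (ACTIVE, INACTIVE):
            bad = t if t not in (ACTIVE, INACTIVE) else p
            raise ValueError(f"labels must be Active/Inactive, got {bad!r}")
        if t == ACTIVE:
            if p == ACTIVE:
                tp += 1
            else:
                fn += 1
        else:
            if p == ACTIVE:
                fp += 1
            else:
                tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient in [-1, 1].

    ``(TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))``; returns 0.0 when
    any marginal factor of the denominator is zero (standard convention).
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    num = cm.tp * cm.tn - cm.fp * cm.fn
    den = (cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    if den == 0:
        return 0.0
    return num / math.sqrt(den)


def ppv(cm: ConfusionMatrix) -> float:
    """Positive predictive value TP/(TP+FP); 0.0 with a warning when no
    compound was predicted Active (so screening sweeps never abort)."""
    denom = cm.tp + cm.fp
    if denom == 0:
        logger.warning("PPV undefined (tp+fp=0); returning 0.0 by convention")
        return 0.0
    return cm.tp / denom


def error_count(cm: ConfusionMatrix) -> int:
    """Total misclassifications FP + FN."""
    return cm.fp + cm.fn


def fp_reduction_percent(
    cm_reduced: ConfusionMatrix, cm_reference: ConfusionMatrix
) -> float:
    """Relative reduction in false positives, in percent, of ``cm_reduced``
    versus ``cm_reference`` (reference must have FP > 0)."""
    if cm_reference.fp <= 0:
        raise ValueError("reference confusion matrix must have fp > 0")
    return 100.0 * (cm_reference.fp - cm_reduced.fp) / cm_reference.fp


def accuracy(cm: ConfusionMatrix) -> float:
    """(TP+TN)/total."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return (cm.tp + cm.tn) / cm.total


def metric_report(cm: ConfusionMatrix) -> dict[str, float | int | dict[str, int]]:
    """Bundle of every reported measure for one evaluation."""
    return {
        "confusion_matrix": cm.as_dict(),
        "mcc": mcc(cm),
        "ppv": ppv(cm),
        "accuracy": accuracy(cm),
        "error_count": error_count(cm),
    }
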