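"""Confusion-matrix evaluation for the gate and behavior classifiers.

The binary gate is scored with overall accuracy
``(TP+TN)/(TP+TN+FP+FN)`` plus two complementary rates used in the
monitoring reports: the *true recognition rate* ``TP/(TP+FP)`` (precision —
of the clips accepted as cattle voice, how many really were) and the
*false recognition rate* ``TN/(TN+FN)`` (negative predictive value — of the
clips rejected as noise, how many really were noise).  Reported percentages
are truncated (not rounded) to two decimals; full precision is kept
internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import DataError, UndefinedRateError

__all__ = [
    "ConfusionMatrix2",
    "ConfusionMatrixK",
    "accuracy",
    "true_recognition_rate",
    "false_recognition_rate",
    "confusion_from_predictions",
    "truncate_percent",
]

#: Behavioral class names, by index.
BEHAVIOR_CLASSES = ("estrus", "food_anticipating", "cough", "normal")


def truncate_percent(value: float) -> float:
    """Truncate a percentage to 2 decimals (91.388... -> 91.38)."""
    return math.floor(value * 100.0 + 1e-9) / 100.0


@dataclass(frozen=True)
class ConfusionMatrix2:
    """2x2 confusion counts for the binary voice/noise gate."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise DataError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def accuracy(cm: ConfusionMatrix2, truncate: bool = True) -> float:
    """Overall accuracy in percent: 100 (TP+TN) / (TP+TN+FP+FN)."""
    if cm.total == 0:
        raise UndefinedRateError("empty confusion matrix")
    value = 100.0 * (cm.tp + cm.tn) / cm.total
    return truncate_percent(value) if truncate else value


def true_recognition_rate(cm: ConfusionMatrix2, truncate: bool = True) -> float:
    """Precision in percent: 100 TP / (TP+FP)."""
    if cm.tp + cm.fp == 0:
        raise UndefinedRateError("no positive predictions")
    value = 100.0 * cm.tp / (cm.tp + cm.fp)
    return truncate_percent(value) if truncate else value


def false_recognition_rate(cm: ConfusionMatrix2, truncate: bool = True) -> float:
    """Negative predictive value in percent: 100 TN / (TN+FN)."""
    if cm.tn + cm.fn == 0:
        raise UndefinedRateError("no negative predictions")
    value = 100.0 * cm.tn / (cm.tn + cm.fn)
    return truncate_percent(value) if truncate else value


@dataclass
class ConfusionMatrixK:
    """K-class confusion counts; rows = true class, columns = predicted."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise DataError("counts must be a square matrix")
        if np.any(self.counts < 0):
            raise DataError("counts must be non-negative")

    @property
    def k(self) -> int:
        return self.counts.shape[0]

    def per_class_accuracy(self) -> np.ndarray:
        """Diagonal / row totals, in percent (NaN for empty classes)."""
        row = self.counts.sum(axis=1).astype(np.float64)
        with np.errstate(invalid="ignore", divide="ignore"):
            return 100.0 * np.diag(self.counts) / row

    def overall_accuracy(self) -> float:
        total = self.counts.sum()
        if total == 0:
            raise UndefinedRateError("empty confusion matrix")
        return 100.0 * np.trace(self.counts) / total

    def to_binary(self, positive: int = 1) -> ConfusionMatrix2:
        """Collapse a 2-class matrix to TP/FP/FN/TN semantics."""
        if self.k != 2:
            raise DataError("to_binary requires a 2x2 matrix")
        p, n = positive, 1 - positive
        return ConfusionMatrix2(
            tp=int(self.counts[p, p]),
            fp=int(self.counts[n, p]),
            fn=int(self.counts[p, n]),
            tn=int(self.counts[n, n]),
        )


def confusion_from_predictions(
    labels, predictions, k: int
) -> tuple[ConfusionMatrixK, np.ndarray]:
    """Count (true, predicted) pairs; returns the matrix and per-class accuracy."""
    y = np.asarray(labels, dtype=np.int64)
    p = np.asarray(predictions, dtype=np.int64)
    if y.shape != p.shape:
        raise DataError("labels and predictions must have the same length")
    if y.size == 0:
        raise DataError("empty label list")
    if np.any((y < 0) | (y >= k)) or np.any((p < 0) | (p >= k)):
        raise DataError(f"labels/predictions must lie in 0..{k - 1}")
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (y, p), 1)
    cm = ConfusionMatrixK(counts=counts)
    return cm, cm.per_class_accuracy()
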