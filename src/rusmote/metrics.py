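"""Confusion-matrix evaluation for imbalanced two-class problems.

The positive class (+1) is the minority (nodule) class.  Besides overall
accuracy, the suite reports the per-class accuracies acc+ (= TPR = recall)
and acc- (= TNR), their geometric mean (G-mean), and precision/recall with
the F-measure — the measures that stay informative when the negative class
dominates the sample.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["ConfusionMatrix", "MetricReport", "confusion", "evaluate"]


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FN/FP/TN counts with +1 as the positive (nodule) class."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.fp + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.tp + other.tp, self.fn + other.fn,
                               self.fp + other.fp, self.tn + other.tn)


@dataclass(frozen=True)
class MetricReport:
    """Evaluation measures; a value is ``None`` when its denominator is 0."""

    accuracy: float | None
    tpr: float | None
    fpr: float | None
    acc_plus: float | None
    acc_minus: float | None
    g_mean: float | None
    precision: float | None
    recall: float | None
    f_measure: float | None

    def as_dict(self) -> dict[str, float | None]:
        return {
            "accuracy": self.accuracy, "tpr": self.tpr, "fpr": self.fpr,
            "acc_plus": self.acc_plus, "acc_minus": self.acc_minus,
            "g_mean": self.g_mean, "precision": self.precision,
            "recall": self.recall, "f_measure": self.f_measure,
        }

    def rounded(self, ndigits: int = 4) -> dict[str, float | None]:
        return {k: (None if v is None else round(v, ndigits))
                for k, v in self.as_dict().items()}


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMatrix:
    """Tally TP/FN/FP/TN from paired {+1, -1} label sequences."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        bad = set(np.unique(arr)) - {1, -1}
        if bad:
            raise ValueError(f"{name} contains invalid labels: {sorted(bad)}")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == -1)))
    fp = int(np.sum((y_true == -1) & (y_pred == 1)))
    tn = int(np.sum((y_true == -1) & (y_pred == -1)))
    return ConfusionMatrix(tp, fn, fp, tn)


def _ratio(num: int, den: int, name: str) -> float | None:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator)", stacklevel=3)
        return None
    return num / den


def evaluate(cm: ConfusionMatrix) -> MetricReport:
    """All evaluation measures from a confusion matrix.

    Zero-denominator measures are reported as ``None`` with a warning, never
    silently as 0.  F-measure is 0 when precision = recall = 0 but both are
    defined.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    accuracy = (cm.tp + cm.tn) / cm.total
    acc_plus = _ratio(cm.tp, cm.n_positive, "acc+ / TPR / recall")
    acc_minus = _ratio(cm.tn, cm.n_negative, "acc-")
    fpr = None if acc_minus is None else cm.fp / cm.n_negative
    g_mean = (None if acc_plus is None or acc_minus is None
              else math.sqrt(acc_plus * acc_minus))
    precision = _ratio(cm.tp, cm.tp + cm.fp, "precision")
    recall = acc_plus
    if precision is None or recall is None:
        f_measure = None
    elif precision + recall == 0:
        f_measure = 0.0
    else:
        f_measure = 2 * precision * recall / (precision + recall)
    return MetricReport(accuracy, acc_plus, fpr, acc_plus, acc_minus,
                        g_mean, precision, recall, f_measure)
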