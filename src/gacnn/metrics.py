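"""Confusion-matrix evaluation for the binary benign/malignant task.

Malignant (label 1) is the positive class: a false negative is a cancer
missed, a false positive a benign case flagged.  Ratios with a zero
denominator are reported as ``nan`` (rendered "n/a" in CSV reports)
rather than silently coerced to 0, so sweep tables cannot hide
degenerate cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "confusion",
    "accuracy",
    "error_rate",
    "recall",
    "precision",
    "f1",
    "evaluate",
    "write_report",
    "REPORT_COLUMNS",
]

BENIGN, MALIGNANT = 0, 1

REPORT_COLUMNS = [
    "optimizer",
    "batch_size",
    "iterations",
    "seed",
    "accuracy",
    "recall",
    "precision",
    "f1",
    "error_rate",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(y_true, y_pred) -> ConfusionMatrix:
    """Count TP/FP/TN/FN with malignant=1 as the positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        if not np.isin(arr, (BENIGN, MALIGNANT)).all():
            raise ValueError(f"{name} contains labels outside {{0, 1}}")
    return ConfusionMatrix(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def accuracy(cm: ConfusionMatrix) -> float:
    """(TP+TN) / total."""
    return _ratio(cm.tp + cm.tn, cm.total)


def error_rate(cm: ConfusionMatrix) -> float:
    """(FP+FN) / total — the genetic algorithm's fitness function."""
    return _ratio(cm.fp + cm.fn, cm.total)


def recall(cm: ConfusionMatrix) -> float:
    """TP / (TP+FN): fraction of malignant cases caught."""
    return _ratio(cm.tp, cm.tp + cm.fn)


def precision(cm: ConfusionMatrix) -> float:
    """TP / (TP+FP): fraction of malignant calls that are right."""
    return _ratio(cm.tp, cm.tp + cm.fp)


def f1(arg1, arg2=None) -> float:
    """Harmonic mean of recall and precision.

    Accepts either a ConfusionMatrix or the pair ``(recall, precision)``.
    """
    if isinstance(arg1, ConfusionMatrix):
        r, p = recall(arg1), precision(arg1)
    else:
        r, p = float(arg1), float(arg2)
    if math.isnan(r) or math.isnan(p) or (r + p) == 0:
        return math.nan
    return 2.0 * r * p / (r + p)


def evaluate(y_true, y_pred) -> dict:
    """All scalar metrics for one pair of label vectors."""
    cm = confusion(y_true, y_pred)
    return {
        "accuracy": accuracy(cm),
        "recall": recall(cm),
        "precision": precision(cm),
        "f1": f1(cm),
        "error_rate": error_rate(cm),
        "confusion": cm,
    }


def write_report(rows: list[dict], path) -> pd.DataFrame:
    """Write evaluation rows to CSV with a stable schema; nan -> "n/a"."""
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    out = df.copy()
    for col in ("accuracy", "recall", "precision", "f1", "error_rate"):
        out[col] = [
            "n/a" if (isinstance(v, float) and math.isnan(v)) else v for v in out[col]
        ]
    out.to_csv(path, index=False)
    return df
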