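"""Confusion matrix and the five evaluation metrics.

ACP is the positive class throughout: TP counts anticancer peptides
predicted anticancer, FP counts non-anticancer peptides predicted
anticancer.  Metrics are accuracy, sensitivity (recall on ACP),
specificity, F1 and the Matthews correlation coefficient.  Ratios with a
zero denominator are reported as NaN together with the reason, never
silently as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .alphabet import ACP, LABELS, NACP

__all__ = ["ConfusionMatrix", "MetricsReport", "confusion", "metrics", "evaluate_predictions"]


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/TN/FP/FN counts with ACP as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def as_text(self) -> str:
        w = max(len(str(v)) for v in (self.tp, self.tn, self.fp, self.fn))
        return (
            f"            pred ACP  pred NACP\n"
            f"true ACP   {self.tp:>{w + 6}}  {self.fn:>{w + 8}}\n"
            f"true NACP  {self.fp:>{w + 6}}  {self.tn:>{w + 8}}\n"
        )


@dataclass(frozen=True)
class MetricsReport:
    """Five-metric report; undefined ratios are NaN with a reason recorded."""

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    mcc: float
    undefined: dict[str, str] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "f1": self.f1,
            "mcc": self.mcc,
        }

    def as_percent_text(self) -> str:
        """Human-readable report, percentages to 2 decimals (MCC on [-1, 1])."""
        lines = []
        for name, value in self.as_dict().items():
            if math.isnan(value):
                lines.append(f"{name}\tNA ({self.undefined.get(name, 'undefined')})")
            elif name == "mcc":
                lines.append(f"{name}\t{value:.2f}")
            else:
                lines.append(f"{name}\t{value * 100:.2f}")
        return "\n".join(lines) + "\n"

    def write_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("metric\tvalue\n")
            for name, value in self.as_dict().items():
                fh.write(f"{name}\t{value!r}\n")
        return path


def confusion(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    positive: str = ACP,
) -> ConfusionMatrix:
    """Tally a confusion matrix from equal-length label vectors."""
    true_arr = np.asarray(true_labels)
    pred_arr = np.asarray(predicted_labels)
    if true_arr.shape != pred_arr.shape or true_arr.ndim != 1:
        raise ValueError("true and predicted label vectors must be equal-length 1-D")
    known = set(LABELS)
    bad = (set(true_arr.tolist()) | set(pred_arr.tolist())) - known
    if bad:
        raise ValueError(f"unknown label(s): {sorted(bad)}")
    pos_true = true_arr == positive
    pos_pred = pred_arr == positive
    return ConfusionMatrix(
        tp=int(np.sum(pos_true & pos_pred)),
        tn=int(np.sum(~pos_true & ~pos_pred)),
        fp=int(np.sum(~pos_true & pos_pred)),
        fn=int(np.sum(pos_true & ~pos_pred)),
    )


def _ratio(num: float, den: float, name: str, undefined: dict[str, str], reason: str) -> float:
    if den == 0:
        undefined[name] = reason
        return math.nan
    return num / den


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Compute accuracy, sensitivity, specificity, precision, F1 and MCC."""
    if cm.total == 0:
        raise ValueError("cannot compute metrics for an empty confusion matrix")
    tp, tn, fp, fn = cm.tp, cm.tn, cm.fp, cm.fn
    undefined: dict[str, str] = {}

    accuracy = (tp + tn) / cm.total
    sensitivity = _ratio(tp, tp + fn, "sensitivity", undefined, "no positive records")
    specificity = _ratio(tn, tn + fp, "specificity", undefined, "no negative records")
    precision = _ratio(tp, tp + fp, "precision", undefined, "no positive predictions")

    if math.isnan(precision) or math.isnan(sensitivity):
        undefined["f1"] = "precision or recall undefined"
        f1 = math.nan
    else:
        f1 = _ratio(
            2 * precision * sensitivity, precision + sensitivity,
            "f1", undefined, "precision + recall is zero",
        )

    mcc_den = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if mcc_den == 0:
        undefined["mcc"] = "a confusion-matrix margin is zero"
        mcc = math.nan
    else:
        mcc = (tp * tn - fp * fn) / mcc_den

    return MetricsReport(
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        precision=precision,
        f1=f1,
        mcc=mcc,
        undefined=undefined,
    )


def evaluate_predictions(
    true_labels: Sequence[str], predicted_labels: Sequence[str]
) -> tuple[MetricsReport, ConfusionMatrix]:
    cm = confusion(true_labels, predicted_labels)
    return metrics(cm), cm
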