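"""Confusion-matrix construction and the five evaluation measures.

Accuracy, precision, recall, F1 and the false-negative rate (FNR, the
missed-diagnosis rate) computed from TP/FP/FN/TN counts.  Degenerate
denominators yield 0 with an explicit undefined flag instead of raising, so
repeated-split averaging never aborts on a degenerate split.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = ["ConfusionCounts", "MetricsReport", "confusion", "compute_metrics", "truncate"]

METRIC_NAMES = ("accuracy", "precision", "recall", "f1", "fnr")


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion-matrix cell counts for a binary classifier."""

    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "FN", "TN"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass(frozen=True)
class MetricsReport:
    """The five measures plus per-metric defined-ness flags.

    An undefined metric (degenerate denominator) carries value 0.0 and
    ``defined[name] is False``.
    """

    accuracy: float
    precision: float
    recall: float
    f1: float
    fnr: float
    defined: Mapping[str, bool] = field(
        default_factory=lambda: {name: True for name in METRIC_NAMES}
    )

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}

    def rounded(self, decimals: int = 4) -> dict[str, float]:
        """Display form: values rounded to ``decimals`` places."""
        return {k: round(v, decimals) for k, v in self.as_dict().items()}

    def truncated(self, decimals: int = 2) -> dict[str, float]:
        """Display form that truncates (floor) instead of rounding, e.g.
        8/9 -> 0.88 at two decimals."""
        return {k: truncate(v, decimals) for k, v in self.as_dict().items()}


def truncate(x: float, decimals: int = 2) -> float:
    """Truncate ``x`` toward zero at ``decimals`` decimal places."""
    factor = 10**decimals
    return math.trunc(x * factor) / factor


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    """Count the four outcomes; label 1 is the positive (cancer) class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError(
            f"label vectors must be 1-D and equal length, got {y_true.shape} "
            f"and {y_pred.shape}"
        )
    for name, arr in (("y_true", y_true), ("y_pred", y_pred)):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} contains a non-binary entry")
    t = y_true.astype(bool)
    p = y_pred.astype(bool)
    return ConfusionCounts(
        TP=int(np.sum(t & p)),
        FP=int(np.sum(~t & p)),
        FN=int(np.sum(t & ~p)),
        TN=int(np.sum(~t & ~p)),
    )


def _ratio(num: int, den: int) -> tuple[float, bool]:
    if den == 0:
        return 0.0, False
    return num / den, True


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Evaluate the five measures from confusion counts.

    accuracy = (TP+TN)/total, precision = TP/(TP+FP),
    recall = TP/(TP+FN), f1 = 2*TP/(2*TP+FP+FN), fnr = FN/(TP+FN).
    """
    if c.total == 0:
        raise ValueError("all-zero confusion counts")
    accuracy, acc_ok = _ratio(c.TP + c.TN, c.total)
    precision, prec_ok = _ratio(c.TP, c.TP + c.FP)
    recall, rec_ok = _ratio(c.TP, c.TP + c.FN)
    f1, f1_ok = _ratio(2 * c.TP, 2 * c.TP + c.FP + c.FN)
    fnr, fnr_ok = _ratio(c.FN, c.TP + c.FN)
    return MetricsReport(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=f1,
        fnr=fnr,
        defined={
            "accuracy": acc_ok,
            "precision": prec_ok,
            "recall": rec_ok,
            "f1": f1_ok,
            "fnr": fnr_ok,
        },
    )
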