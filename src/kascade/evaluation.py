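"""Binary confusion counting and the four standard PTM-prediction metrics.

Sn = TP / (TP + FN)            (sensitivity / recall on acetylated sites)
Sp = TN / (TN + FP)            (specificity on non-acetylated sites)
Acc = (TP + TN) / total
MCC = (TP*TN - FP*FN) / sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN))

Precision TP / (TP + FP) is also exposed.  When any factor of the MCC radical
is zero the coefficient is reported as 0 with a ``degenerate`` flag rather
than NaN (the common convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    sn: float
    sp: float
    acc: float
    mcc: float
    precision: float
    mcc_degenerate: bool
    counts: ConfusionCounts

    def as_dict(self, percent: bool = False) -> dict[str, float]:
        scale = 100.0 if percent else 1.0
        return {
            "Sn": self.sn * scale,
            "Sp": self.sp * scale,
            "Acc": self.acc * scale,
            "MCC": self.mcc,
            "precision": self.precision * scale,
        }

    def format_row(self) -> str:
        """Percent rendering with 2 decimals, matching the field's result tables."""
        return (
            f"{self.sn * 100:.2f}\t{self.sp * 100:.2f}\t{self.acc * 100:.2f}\t{self.mcc:.4f}"
        )


def confusion(y_true, y_pred) -> ConfusionCounts:
    """2x2 confusion counts for binary 0/1 label vectors of equal length."""
    yt = np.asarray(y_true, dtype=int)
    yp = np.asarray(y_pred, dtype=int)
    if yt.shape != yp.shape or yt.ndim != 1:
        raise ValueError(f"label vectors must be 1-D and equal length, got {yt.shape} vs {yp.shape}")
    for arr, name in ((yt, "y_true"), (yp, "y_pred")):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} must contain only 0/1 labels")
    return ConfusionCounts(
        tp=int(np.sum((yt == 1) & (yp == 1))),
        tn=int(np.sum((yt == 0) & (yp == 0))),
        fp=int(np.sum((yt == 0) & (yp == 1))),
        fn=int(np.sum((yt == 1) & (yp == 0))),
    )


def metrics(counts: ConfusionCounts) -> MetricsReport:
    """Sn, Sp, Acc, MCC (and precision) from confusion counts.

    A metric whose denominator is empty (e.g. Sn with no positive samples) is
    reported as 0.  Any zero factor in the MCC radical yields MCC = 0 with
    ``mcc_degenerate=True``.
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    if counts.total == 0:
        raise ValueError("cannot compute metrics from all-zero counts")

    def _ratio(num: int, den: int) -> float:
        return num / den if den else 0.0

    sn = _ratio(tp, tp + fn)
    sp = _ratio(tn, tn + fp)
    acc = (tp + tn) / counts.total
    prec = _ratio(tp, tp + fp)
    factors = (tp + fn, tn + fp, tp + fp, tn + fn)
    degenerate = 0 in factors
    if degenerate:
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(math.prod(factors))
    return MetricsReport(
        sn=sn, sp=sp, acc=acc, mcc=mcc, precision=prec,
        mcc_degenerate=degenerate, counts=counts,
    )


def evaluate(y_true, y_pred) -> MetricsReport:
    """Convenience: :func:`confusion` followed by :func:`metrics`."""
    return metrics(confusion(y_true, y_pred))
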