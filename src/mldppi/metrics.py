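"""The seven binary-classification evaluation measures used for PPI models.

From a confusion matrix (TP, FP, TN, FN) we report overall accuracy (ACC),
sensitivity (SN), specificity (Spec), positive and negative predictive
value (PPV, NPV), the F-score (harmonic mean of SN and PPV) and Matthews'
correlation coefficient (MCC). A metric whose denominator is zero is
reported as 0 and flagged ``undefined`` — never a silent NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

METRIC_NAMES = ("acc", "sn", "spec", "ppv", "npv", "f_score", "mcc")


@dataclass(frozen=True)
class ConfusionCounts:
    """Cell counts of a binary confusion matrix."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricReport:
    """The seven metrics as fractions, plus the set of undefined ones."""

    acc: float
    sn: float
    spec: float
    ppv: float
    npv: float
    f_score: float
    mcc: float
    undefined: frozenset[str] = field(default_factory=frozenset)

    def as_dict(self, percent: bool = False) -> dict[str, float]:
        scale = 100.0 if percent else 1.0
        return {name: scale * getattr(self, name) for name in METRIC_NAMES}


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Tally TP/FP/TN/FN from two equal-length binary vectors."""
    yt = np.asarray(y_true, dtype=int)
    yp = np.asarray(y_pred, dtype=int)
    if yt.shape != yp.shape or yt.ndim != 1:
        raise ValueError(f"shape mismatch: {yt.shape} vs {yp.shape}")
    for name, v in (("y_true", yt), ("y_pred", yp)):
        if not np.isin(v, (0, 1)).all():
            raise ValueError(f"{name} must contain only 0/1")
    return ConfusionCounts(
        tp=int(((yt == 1) & (yp == 1)).sum()),
        fp=int(((yt == 0) & (yp == 1)).sum()),
        tn=int(((yt == 0) & (yp == 0)).sum()),
        fn=int(((yt == 1) & (yp == 0)).sum()),
    )


def _ratio(num: float, den: float, name: str, undefined: set[str]) -> float:
    if den == 0:
        undefined.add(name)
        return 0.0
    return num / den


def metrics(c: ConfusionCounts) -> MetricReport:
    """Compute ACC, SN, Spec, PPV, NPV, F-score and MCC from counts.

    ACC = (TP+TN)/total, SN = TP/(TP+FN), Spec = TN/(TN+FP),
    PPV = TP/(TP+FP), NPV = TN/(TN+FN), F = 2·SN·PPV/(SN+PPV),
    MCC = (TP·TN − FP·FN) / sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN)).
    """
    if c.total == 0:
        raise ValueError("cannot compute metrics from an empty confusion matrix")
    undefined: set[str] = set()
    acc = (c.tp + c.tn) / c.total
    sn = _ratio(c.tp, c.tp + c.fn, "sn", undefined)
    spec = _ratio(c.tn, c.tn + c.fp, "spec", undefined)
    ppv = _ratio(c.tp, c.tp + c.fp, "ppv", undefined)
    npv = _ratio(c.tn, c.tn + c.fn, "npv", undefined)
    f_score = _ratio(2 * sn * ppv, sn + ppv, "f_score", undefined)
    mcc_den = math.sqrt(
        float(c.tp + c.fn) * (c.tn + c.fp) * (c.tp + c.fp) * (c.tn + c.fn)
    )
    mcc = _ratio(c.tp * c.tn - c.fp * c.fn, mcc_den, "mcc", undefined)
    return MetricReport(acc, sn, spec, ppv, npv, f_score, mcc, frozenset(undefined))
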