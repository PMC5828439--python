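"""Confusion-matrix performance measures for the binary classifier.

Positive class is "neuropathic". Counts may be fractional when they are
means over repeated cross-validation runs. A rate whose denominator is
zero is undefined and reported as NaN, never coerced to 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN tallies (nonnegative, fractional allowed)."""

    tp: float
    fp: float
    tn: float
    fn: float

    def __post_init__(self) -> None:
        vals = (self.tp, self.fp, self.tn, self.fn)
        if any(v < 0 or not math.isfinite(v) for v in vals):
            raise ValueError(f"confusion counts must be finite and nonnegative: {vals}")
        if sum(vals) == 0:
            raise ValueError("confusion counts are all zero")

    @property
    def total(self) -> float:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class PerformanceReport:
    """Derived rates: sensitivity/specificity of both classes, accuracy,
    Matthews correlation coefficient, and the ROC point (TPR, FPR).

    sn_pos = TP/(TP+FN) and sp_pos = TP/(TP+FP) describe the positive
    (neuropathic) class; sn_neg = TN/(TN+FP) and sp_neg = TN/(TN+FN) the
    negative class. tpr coincides with sn_pos by definition.
    """

    sn_pos: float
    sp_pos: float
    sn_neg: float
    sp_neg: float
    ac: float
    mcc: float
    tpr: float
    fpr: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def compute_metrics(c: ConfusionCounts) -> PerformanceReport:
    """All performance measures from one set of confusion counts.

    MCC = (TP·TN − FP·FN) / sqrt((TP+FN)(TP+FP)(TN+FN)(TN+FP)); when any
    marginal is zero the MCC is undefined (NaN), not zero.
    """
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    denom = (tp + fn) * (tp + fp) * (tn + fn) * (tn + fp)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom > 0 else math.nan
    sn_pos = _ratio(tp, tp + fn)
    return PerformanceReport(
        sn_pos=sn_pos,
        sp_pos=_ratio(tp, tp + fp),
        sn_neg=_ratio(tn, tn + fp),
        sp_neg=_ratio(tn, tn + fn),
        ac=_ratio(tp + tn, c.total),
        mcc=mcc,
        tpr=sn_pos,
        fpr=_ratio(fp, fp + tn),
    )


def confusion_from_predictions(pairs) -> ConfusionCounts:
    """Tally (true_label, predicted_label) pairs; positive = neuropathic."""
    tp = fp = tn = fn = 0
    for true, pred in pairs:
        if true not in ("normal", "neuropathic") or pred not in ("normal", "neuropathic"):
            raise ValueError(f"unknown label in pair ({true!r}, {pred!r})")
        if true == "neuropathic":
            if pred == "neuropathic":
                tp += 1
            else:
                fn += 1
        else:
            if pred == "neuropathic":
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
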