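"""Confusion-matrix accuracy accounting for labeled bioset calls."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .core_io import SigscreenError
from .screening import CALL_ACTIVATED, CALL_NEUTRAL, CALL_SUPPRESSED

_TRUTHS = ("positive", "negative")
_CALLS = (CALL_ACTIVATED, CALL_SUPPRESSED, CALL_NEUTRAL)


@dataclass(frozen=True)
class LabeledCall:
    bioset_id: str
    truth: str  # "positive" | "negative"
    call: str  # "activated" | "suppressed" | "neutral"

    def __post_init__(self) -> None:
        if self.truth not in _TRUTHS:
            raise SigscreenError(f"truth must be one of {_TRUTHS}, got {self.truth!r}")
        if self.call not in _CALLS:
            raise SigscreenError(f"call must be one of {_CALLS}, got {self.call!r}")


@dataclass(frozen=True)
class AccuracyReport:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    balanced_accuracy: float

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "balanced_accuracy": self.balanced_accuracy,
        }


def percent(proportion: float) -> float:
    """Whole-percent presentation with half-up rounding (0.9583 -> 96)."""
    if math.isnan(proportion):
        return math.nan
    return float(math.floor(proportion * 100 + 0.5))


def evaluate(
    calls: Sequence[LabeledCall], positive_means: str = "activated"
) -> AccuracyReport:
    """Sensitivity/specificity/balanced accuracy of the calls.

    ``positive_means`` selects what counts as a positive prediction:
    ``"activated"`` (the default — a truth-positive called suppressed is a
    false negative) or ``"activated_or_suppressed"``.  With no positives or
    no negatives the undefined ratio (and balanced accuracy) is NaN.
    """
    if positive_means not in ("activated", "activated_or_suppressed"):
        raise SigscreenError(f"unknown positive_means {positive_means!r}")
    ids = [c.bioset_id for c in calls]
    if len(set(ids)) != len(ids):
        raise SigscreenError("duplicate bioset_id in calls")

    def predicted_positive(call: str) -> bool:
        if positive_means == "activated":
            return call == CALL_ACTIVATED
        return call != CALL_NEUTRAL

    tp = fp = tn = fn = 0
    for c in calls:
        pred = predicted_positive(c.call)
        if c.truth == "positive":
            tp, fn = tp + pred, fn + (not pred)
        else:
            fp, tn = fp + pred, tn + (not pred)

    sens = tp / (tp + fn) if (tp + fn) else math.nan
    spec = tn / (tn + fp) if (tn + fp) else math.nan
    bal = (sens + spec) / 2.0
    return AccuracyReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=sens, specificity=spec, balanced_accuracy=bal,
    )
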