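"""Day-level scoring of the wetting-moment estimators.

Block-level decisions are not comparable across estimators (the rule-based
ones emit flags, the deep one probabilities), but whether a whole night was
enuretic is known ground truth, so estimators are scored at the day level: a
night is predicted enuretic when any block is positive (rule estimators) or
any block probability exceeds the alarm threshold (deep estimator).  The
reduction is configurable to "at least k positive blocks".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimators import WindowDecision

__all__ = ["DayPrediction", "DayMetrics", "day_level_decision", "day_metrics"]


@dataclass
class DayPrediction:
    night_id: str
    predicted_ne_day: bool
    truth_ne_day: bool
    first_alarm_time: float | None   # present iff predicted_ne_day

    def __post_init__(self) -> None:
        if self.predicted_ne_day != (self.first_alarm_time is not None):
            raise ValueError("first_alarm_time must be present iff predicted_ne_day")


@dataclass
class DayMetrics:
    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    precision: float | None   # None when undefined (zero denominator)
    recall: float | None

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def day_level_decision(
    decisions: list[WindowDecision],
    truth_ne_day: bool,
    night_id: str = "",
    alarm_threshold: float = 0.85,
    min_positive_blocks: int = 1,
) -> DayPrediction:
    """Reduce one night's block decisions to a day-level prediction.

    A block counts as positive when its flag is True (rule estimators) or
    its probability is strictly greater than ``alarm_threshold`` (deep
    estimator).  The night is predicted enuretic when at least
    ``min_positive_blocks`` blocks are positive; the first alarm time is the
    earliest positive block's start.
    """
    if not decisions:
        raise ValueError("no block decisions for this night")
    positive_times = []
    for d in decisions:
        if d.probability is not None:
            pos = d.probability > alarm_threshold
        else:
            pos = bool(d.positive) if d.positive is not None else False
        if pos:
            positive_times.append(d.start_time)
    predicted = len(positive_times) >= min_positive_blocks
    return DayPrediction(
        night_id=night_id,
        predicted_ne_day=predicted,
        truth_ne_day=truth_ne_day,
        first_alarm_time=min(positive_times) if predicted else None,
    )


def day_metrics(predictions: list[DayPrediction]) -> DayMetrics:
    """Accuracy, precision and recall from the 2x2 day-level confusion table.

    Undefined ratios (zero denominators) come back as ``None`` rather than
    NaN-propagating.
    """
    if not predictions:
        raise ValueError("need at least one day prediction")
    tp = sum(p.predicted_ne_day and p.truth_ne_day for p in predictions)
    fp = sum(p.predicted_ne_day and not p.truth_ne_day for p in predictions)
    fn = sum(not p.predicted_ne_day and p.truth_ne_day for p in predictions)
    tn = sum(not p.predicted_ne_day and not p.truth_ne_day for p in predictions)
    total = tp + fp + fn + tn
    return DayMetrics(
        tp=tp, fp=fp, fn=fn, tn=tn,
        accuracy=(tp + tn) / total,
        precision=tp / (tp + fp) if tp + fp else None,
        recall=tp / (tp + fn) if tp + fn else None,
    )
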