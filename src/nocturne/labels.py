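"""Linear enuresis-probability labels and the alarm rule.

Bedwetting happens at most once or twice in an ~8-hour night, so discrete
window classes would be hopelessly imbalanced.  Instead each window gets a
continuous target: the probability that wetting is imminent, drawn from a
linear-in-time model.

* Enuretic night: probability rises linearly from the start anchor (0) to
  1.0 exactly at the wetting moment; windows after the wetting moment are
  excluded from supervised targets (collection effectively ends at the
  event).
* Dry night: probability rises linearly from 0 to 0.70 at the end of
  collection — clinical advice puts the end-of-night risk on a dry night at
  70%.

Probabilities are normalized to [0, 1].  When the probability exceeds 0.85
the model says wetting will occur soon — that is the alarm rule (strictly
greater than the threshold).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .session import SensorNight, WindowGrid, resample_and_align

__all__ = ["LabelConfig", "NEProbabilityCurve", "probability_curve", "alarm_windows"]


@dataclass(frozen=True)
class LabelConfig:
    dry_end_probability: float = 0.70
    alarm_threshold: float = 0.85
    ne_start_probability: float = 0.0   # anchor at collection start

    def __post_init__(self) -> None:
        if not 0.0 < self.dry_end_probability < 1.0:
            raise ValueError("dry_end_probability must be in (0, 1)")
        if not 0.0 < self.alarm_threshold < 1.0:
            raise ValueError("alarm_threshold must be in (0, 1)")
        if not 0.0 <= self.ne_start_probability < 1.0:
            raise ValueError("ne_start_probability must be in [0, 1)")


@dataclass
class NEProbabilityCurve:
    """Per-window target probability plus a mask of windows usable as targets."""

    p: np.ndarray              # in [0, 1], one entry per window
    target_mask: np.ndarray    # False for post-wetting windows
    window_ends: np.ndarray
    night_id: str
    is_ne_day: bool


def probability_curve(
    night: SensorNight,
    grid: WindowGrid | None = None,
    config: LabelConfig = LabelConfig(),
) -> NEProbabilityCurve:
    """The linear per-window probability targets for one night.

    Window probabilities are evaluated at window end times.  On an enuretic
    night the window containing the wetting moment gets probability 1.0 and
    later windows are masked out of the supervised targets.
    """
    if grid is None:
        grid = resample_and_align(night)
    t = grid.window_ends
    mask = np.ones(grid.n_windows, dtype=bool)
    if night.is_ne_day:
        ne = night.ne_moment
        if ne is None or not (0.0 < ne <= night.collection_span):
            raise ValueError("enuretic night requires ne_moment within the collection span")
        p0 = config.ne_start_probability
        p = p0 + (1.0 - p0) * t / ne
        p = np.clip(p, 0.0, 1.0)
        mask = grid.window_starts <= ne  # keep the window containing the moment
    else:
        p = config.dry_end_probability * t / (grid.n_windows * grid.window_length)
        p = np.clip(p, 0.0, 1.0)
    return NEProbabilityCurve(
        p=p,
        target_mask=mask,
        window_ends=t,
        night_id=night.night_id,
        is_ne_day=night.is_ne_day,
    )


def alarm_windows(p_series: np.ndarray, threshold: float = 0.85) -> np.ndarray:
    """Window indices whose probability is strictly greater than ``threshold``."""
    p = np.asarray(p_series, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    return np.flatnonzero(p > threshold)
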