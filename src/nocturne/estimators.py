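"""Rule-based wetting-moment estimators over 10-minute sliding blocks.

All estimators consume blocks of 20 consecutive 30-s feature windows
(10 minutes), slid by one window (30 s).  Four rule-based estimators combine
per-modality conditions by AND:

===========  ==================================
estimator    conditions used
===========  ==================================
RE_B         bladder
RE_BL        bladder AND limb movement
RE_BH        bladder AND heart rate
RE_ALL       bladder AND heart rate AND limb movement
===========  ==================================

* bladder condition — the cumulative clipped-difference feature (BID) at the
  block end has fallen to or below a threshold ``theta_bid`` (more negative
  means a fuller bladder);
* heart-rate condition — the block mean heart rate is at least
  ``theta_hr`` bpm above the night's opening baseline;
* limb-movement condition — at least ``theta_lm`` movements were counted in
  the block.

Because each estimator's condition set is a superset of RE_B's, positive
blocks are nested: RE_ALL ⊆ RE_BH ⊆ RE_B and RE_ALL ⊆ RE_BL ⊆ RE_B.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import ALL_FEATURES, BV_FEATURES, LM_FEATURES
from .heart import HRV_FEATURES

__all__ = [
    "BLOCK_WINDOWS",
    "EstimatorBlock",
    "RuleConfig",
    "WindowDecision",
    "RULE_ESTIMATORS",
    "RULE_INPUTS",
    "make_blocks",
    "rule_estimate",
    "rule_estimate_night",
    "hr_baseline",
    "calibrate_theta_bid",
]

log = logging.getLogger(__name__)

BLOCK_WINDOWS = 20  # 10 min of 30-s windows

RULE_ESTIMATORS = ("RE_B", "RE_BL", "RE_BH", "RE_ALL")

#: which modalities each estimator consults (mirrors the estimator design table)
RULE_INPUTS = {
    "RE_B": ("bv",),
    "RE_BL": ("bv", "lm"),
    "RE_BH": ("bv", "hr"),
    "RE_ALL": ("bv", "hr", "lm"),
    "DE": ("bv", "hr", "lm"),
}


@dataclass
class EstimatorBlock:
    """Twenty consecutive windows of the feature frame."""

    start_window: int
    start_time: float            # s, start of the first window
    end_time: float              # s, end of the last window
    features: pd.DataFrame       # BLOCK_WINDOWS rows, feature columns
    complete: bool               # no missing windows

    @property
    def bv(self) -> pd.DataFrame:
        return self.features[list(BV_FEATURES)]

    @property
    def hrv(self) -> pd.DataFrame:
        return self.features[list(HRV_FEATURES)]

    @property
    def lm(self) -> pd.DataFrame:
        return self.features[list(LM_FEATURES)]


@dataclass(frozen=True)
class RuleConfig:
    """Thresholds for the rule-based estimators.

    ``theta_bid`` (ohm) — bladder-almost-full bound on the cumulative BID;
    ``theta_hr`` (bpm) — rise over the night baseline; ``theta_lm`` (count)
    — movements per block.
    """

    theta_bid: float = -30.0
    theta_hr: float = 5.0
    theta_lm: int = 1

    def __post_init__(self) -> None:
        # -inf is allowed (it makes a condition unsatisfiable); NaN is not
        if np.isnan(self.theta_bid) or np.isnan(self.theta_hr):
            raise ValueError("rule thresholds must not be NaN")


@dataclass
class WindowDecision:
    """One estimator's verdict for one block."""

    start_time: float
    estimator: str
    positive: bool | None        # None = missing (incomplete block/modality)
    probability: float | None = None  # deep estimator only


def make_blocks(frame: pd.DataFrame) -> list[EstimatorBlock]:
    """All 10-minute blocks of a feature frame (count = n_windows - 19).

    A frame shorter than 20 windows yields no blocks, with a warning.
    """
    n = len(frame)
    if n < BLOCK_WINDOWS:
        warnings.warn(
            f"frame has {n} windows < {BLOCK_WINDOWS}; no blocks", stacklevel=2
        )
        return []
    blocks = []
    window_len = float(frame["time"].iloc[0]) if n else 30.0
    for i in range(n - BLOCK_WINDOWS + 1):
        sub = frame.iloc[i : i + BLOCK_WINDOWS]
        blocks.append(
            EstimatorBlock(
                start_window=i,
                start_time=float(sub["time"].iloc[0]) - window_len,
                end_time=float(sub["time"].iloc[-1]),
                features=sub,
                complete=not bool(sub["missing"].any()),
            )
        )
    return blocks


def hr_baseline(frame: pd.DataFrame, baseline_windows: int | None = None) -> float:
    """Night heart-rate baseline: mean windowed HR over the opening segment.

    Defaults to the first hour (120 windows) or the first quarter of the
    night, whichever is shorter.
    """
    if baseline_windows is None:
        baseline_windows = max(1, min(120, len(frame) // 4))
    head = frame.loc[~frame["missing"], "hr_mean"].iloc[:baseline_windows]
    return float(head.mean())


def calibrate_theta_bid(frames: list[pd.DataFrame], fraction: float = 0.6) -> float:
    """Bladder-almost-full threshold: ``fraction`` of the most-negative BID
    observed across a calibration set of nights."""
    lows = [
        float(np.nanmin(f.loc[~f["missing"], "BID"]))
        for f in frames
        if (~f["missing"]).any()
    ]
    if not lows:
        raise ValueError("no usable nights in the calibration set")
    return fraction * float(np.min(lows))


def rule_estimate(
    name: str,
    block: EstimatorBlock,
    config: RuleConfig,
    night_baseline: float,
) -> WindowDecision:
    """One rule-based estimator's decision for one block.

    The decision is the AND of the conditions of the modalities the
    estimator consults; a missing required modality (or incomplete block)
    yields a ``None`` decision and a log entry.
    """
    if name not in RULE_ESTIMATORS:
        raise ValueError(f"unknown rule estimator {name!r}")
    needs = RULE_INPUTS[name]
    if not block.complete:
        log.debug("block at %.0fs: incomplete, decision missing", block.start_time)
        return WindowDecision(block.start_time, name, None)

    conditions = []
    bid_end = float(block.features["BID"].iloc[-1])
    if np.isnan(bid_end):
        return WindowDecision(block.start_time, name, None)
    conditions.append(bid_end <= config.theta_bid)

    if "hr" in needs:
        hr_block = float(block.features["hr_mean"].mean())
        if np.isnan(hr_block) or np.isnan(night_baseline):
            log.debug("block at %.0fs: HR missing for %s", block.start_time, name)
            return WindowDecision(block.start_time, name, None)
        conditions.append(hr_block >= night_baseline + config.theta_hr)

    if "lm" in needs:
        lm_count = block.features[["counter_l", "counter_r"]].to_numpy()
        if np.isnan(lm_count).all():
            log.debug("block at %.0fs: LM missing for %s", block.start_time, name)
            return WindowDecision(block.start_time, name, None)
        conditions.append(np.nansum(lm_count) >= config.theta_lm)

    return WindowDecision(block.start_time, name, bool(all(conditions)))


def rule_estimate_night(
    name: str,
    frame: pd.DataFrame,
    config: RuleConfig,
    baseline_windows: int | None = None,
) -> list[WindowDecision]:
    """Run one rule-based estimator over every block of a night."""
    baseline = hr_baseline(frame, baseline_windows)
    return [rule_estimate(name, b, config, baseline) for b in make_blocks(frame)]
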