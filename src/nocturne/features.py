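"""Assemble the 21-feature frame: one row per 30-s window.

Columns (in order): five bladder features ``BI, BID_decrease, BID, DBID,
Clt``; nine HRV features ``hr_max, hr_mean, hr_min, hr_std, nni_20, nni_50,
pnni_20, pnni_50, range_nn``; seven limb-movement features
``angle_trend_l, angle_trend_r, magnitude_l, magnitude_r, counter_l,
counter_r, plms_index`` (the night-level PLMS index broadcast to every
window).  Missing data is flagged per window (``missing`` column), never
silently dropped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import bladder, heart, motion
from .session import SensorNight, WindowGrid, resample_and_align

__all__ = [
    "BV_FEATURES",
    "LM_FEATURES",
    "ALL_FEATURES",
    "extract_features",
]

BV_FEATURES = ("BI", "BID_decrease", "BID", "DBID", "Clt")
LM_FEATURES = (
    "angle_trend_l", "angle_trend_r",
    "magnitude_l", "magnitude_r",
    "counter_l", "counter_r",
    "plms_index",
)
ALL_FEATURES = BV_FEATURES + heart.HRV_FEATURES + LM_FEATURES


def extract_features(
    night: SensorNight,
    grid: WindowGrid | None = None,
    bv_params: bladder.BVParams = bladder.BVParams(),
    motion_params: motion.MotionParams = motion.MotionParams(),
    modalities: tuple[str, ...] = ("bv", "hrv", "lm"),
) -> pd.DataFrame:
    """Windowed feature frame for one night.

    ``modalities`` selects which feature families to compute (others are
    filled with NaN); restricting it speeds up large simulated cohorts when
    only one family is under study.

    The frame carries ``window``, ``time`` (window end, s), the 21 feature
    columns, and a boolean ``missing`` flag; night metadata lives in
    ``frame.attrs``.
    """
    if grid is None:
        grid = resample_and_align(night)
    n = grid.n_windows
    frame = pd.DataFrame(
        {
            "window": np.arange(n),
            "time": grid.window_ends,
        }
    )
    for col in ALL_FEATURES:
        frame[col] = np.nan
    missing = grid.missing.copy()

    if "bv" in modalities:
        bi_rate = night.channel("bi").rate
        bv = bladder.window_bi_features(grid.bi, bi_rate, bv_params)
        for col in BV_FEATURES:
            frame[col] = bv[col]
        frame.attrs["d_upper"] = float(bv["d_upper"][0]) if n else np.nan

    if "hrv" in modalities and grid.beats is not None:
        rows = np.full((n, len(heart.HRV_FEATURES)), np.nan)
        for i, beats in enumerate(grid.beats):
            feats = heart.hrv_window_features(heart.nn_intervals(beats))
            if feats is None:
                missing[i] = True
            else:
                rows[i] = [feats[k] for k in heart.HRV_FEATURES]
        frame[list(heart.HRV_FEATURES)] = rows

    if "lm" in modalities and grid.motion:
        rate = night.channel("accel_l").rate if "accel_l" in night.channels else 100.0
        per_side_events: dict[str, list[motion.LMEvent]] = {}
        for side, acc_name, gyr_name in (
            ("left", "accel_l", "gyro_l"),
            ("right", "accel_r", "gyro_r"),
        ):
            suffix = "l" if side == "left" else "r"
            if acc_name not in night.channels:
                continue
            accel = night.channel(acc_name).samples
            gyro = night.channels.get(gyr_name)
            events = motion.detect_limb_movements(
                accel, gyro.samples if gyro else None, side, rate, motion_params
            )
            per_side_events[side] = events

            frame[f"magnitude_{suffix}"] = [
                motion.movement_magnitude(w, rate, motion_params)
                for w in grid.motion[acc_name]
            ]
            if gyr_name in grid.motion:
                frame[f"angle_trend_{suffix}"] = [
                    motion.angle_difference_trend(w, rate) for w in grid.motion[gyr_name]
                ]
            onsets = np.array([e.onset for e in events])
            counts, _ = np.histogram(
                onsets, bins=np.append(grid.window_starts, n * grid.window_length)
            )
            frame[f"counter_{suffix}"] = counts

        pooled = motion.merge_bilateral(
            [e for ev in per_side_events.values() for e in ev],
            motion_params.bilateral_window,
        )
        hours = n * grid.window_length / 3600.0
        frame["plms_index"] = motion.plms_index(pooled, hours, motion_params)
        frame.attrs["lm_events"] = pooled

    frame["missing"] = missing
    frame.attrs.update(
        subject_id=night.subject_id,
        night_id=night.night_id,
        is_ne_day=night.is_ne_day,
        ne_moment=night.ne_moment,
        collection_span=night.collection_span,
    )
    return frame
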