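"""Limb-movement detection from 6-axis ankle sensors and the PLMS index.

Periodic limb movements in sleep (PLMS) are repetitive stereotyped jerks
occurring in series.  Following AASM-style scoring criteria: a candidate limb
movement (LM) lasts 0.5-10 s; movements qualify as *periodic* when they
belong to a series of at least four LMs with successive onsets 5-90 s apart.
The PLMS index is the number of qualifying movements per hour; an index of
5/h or more is read as a PLMS disorder.

Detection operates on the high-pass-filtered acceleration norm (gravity
removed): a movement is a contiguous span where a short moving-RMS envelope
exceeds a threshold set relative to the quiet-night noise floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "LMEvent",
    "MotionParams",
    "movement_magnitude",
    "detect_limb_movements",
    "merge_bilateral",
    "qualifying_events",
    "plms_index",
    "has_plms_disorder",
    "angle_difference_trend",
]

PLMS_DISORDER_THRESHOLD = 5.0  # events/hour


@dataclass(frozen=True)
class LMEvent:
    """One detected (or planted) limb movement."""

    side: str          # "left" | "right" | "both" (after bilateral merge)
    onset: float       # s from collection start
    duration: float    # s
    magnitude: float   # g, peak envelope


@dataclass(frozen=True)
class MotionParams:
    """Detection tunables.

    The envelope threshold is ``threshold_factor`` times a robust (MAD-based)
    estimate of the quiet-night envelope SD; candidate gates and series rules
    follow the AASM-style criteria above.
    """

    highpass_hz: float = 0.5
    envelope_seconds: float = 0.1
    threshold_factor: float = 8.0
    min_duration: float = 0.5
    max_duration: float = 10.0
    merge_gap: float = 0.5
    series_min_length: int = 4
    series_onset_gap: tuple[float, float] = (5.0, 90.0)
    bilateral_window: float = 0.5


def _highpass_norm(accel: np.ndarray, rate: float, highpass_hz: float) -> np.ndarray:
    """Euclidean norm of the gravity-removed (high-passed) acceleration."""
    accel = np.asarray(accel, dtype=float)
    if accel.size == 0:
        return np.empty(0)
    if np.ptp(accel, axis=0).max(initial=0.0) < 1e-15:
        return np.zeros(accel.shape[0])
    sos = signal.butter(2, highpass_hz, btype="highpass", fs=rate, output="sos")
    filt = signal.sosfiltfilt(sos, accel, axis=0)
    return np.linalg.norm(filt, axis=1)


def movement_magnitude(
    accel: np.ndarray, rate: float = 100.0, params: MotionParams = MotionParams()
) -> float:
    """Mean norm of the high-pass-filtered acceleration over a window (g)."""
    norm = _highpass_norm(accel, rate, params.highpass_hz)
    return float(norm.mean()) if norm.size else 0.0


def _envelope(norm: np.ndarray, rate: float, seconds: float) -> np.ndarray:
    w = max(1, int(round(seconds * rate)))
    kernel = np.ones(w) / w
    return np.sqrt(np.convolve(norm**2, kernel, mode="same"))


def detect_limb_movements(
    accel: np.ndarray,
    gyro: np.ndarray | None,
    side: str,
    rate: float = 100.0,
    params: MotionParams = MotionParams(),
) -> list[LMEvent]:
    """Candidate limb movements on one ankle.

    Spans where the acceleration envelope exceeds the threshold are merged
    when separated by less than ``merge_gap`` seconds, then gated to
    0.5-10 s duration.  The gyroscope is not needed for detection (the
    acceleration envelope carries the burst) but is accepted for interface
    symmetry with the feature extractor.
    """
    norm = _highpass_norm(accel, rate, params.highpass_hz)
    if norm.size == 0:
        return []
    env = _envelope(norm, rate, params.envelope_seconds)
    # the quiet-night envelope has a nonzero noise floor; threshold above it
    floor = np.median(env)
    mad = np.median(np.abs(env - floor))
    noise_sd = 1.4826 * mad
    threshold = floor + params.threshold_factor * max(noise_sd, 1e-12)
    active = env > threshold

    edges = np.diff(np.concatenate(([0], active.view(np.int8), [0])))
    starts = np.flatnonzero(edges == 1)
    stops = np.flatnonzero(edges == -1)
    # merge spans with gaps < merge_gap
    merged: list[list[int]] = []
    gap = int(params.merge_gap * rate)
    for a, b in zip(starts, stops):
        if merged and a - merged[-1][1] < gap:
            merged[-1][1] = b
        else:
            merged.append([a, b])

    events = []
    for a, b in merged:
        duration = (b - a) / rate
        if params.min_duration <= duration <= params.max_duration:
            events.append(
                LMEvent(
                    side=side,
                    onset=a / rate,
                    duration=duration,
                    magnitude=float(env[a:b].max()),
                )
            )
    return events


def merge_bilateral(
    events: list[LMEvent], window: float = 0.5
) -> list[LMEvent]:
    """Pool both ankles: simultaneous bilateral movements (onsets within
    ``window`` s) count once."""
    out: list[LMEvent] = []
    for e in sorted(events, key=lambda e: e.onset):
        if out and e.onset - out[-1].onset < window and e.side != out[-1].side:
            prev = out[-1]
            out[-1] = LMEvent(
                side="both",
                onset=prev.onset,
                duration=max(prev.duration, e.onset + e.duration - prev.onset),
                magnitude=max(prev.magnitude, e.magnitude),
            )
        else:
            out.append(e)
    return out


def qualifying_events(
    events: list[LMEvent], params: MotionParams = MotionParams()
) -> list[LMEvent]:
    """Movements belonging to a periodic series: runs of >= 4 events whose
    successive onsets are 5-90 s apart."""
    ev = sorted(events, key=lambda e: e.onset)
    lo, hi = params.series_onset_gap
    qualifying: list[LMEvent] = []
    run: list[LMEvent] = []

    def flush(run: list[LMEvent]) -> None:
        if len(run) >= params.series_min_length:
            qualifying.extend(run)

    for e in ev:
        if run and lo <= e.onset - run[-1].onset <= hi:
            run.append(e)
        else:
            flush(run)
            run = [e]
    flush(run)
    return qualifying


def plms_index(
    events: list[LMEvent],
    sleep_hours: float,
    params: MotionParams = MotionParams(),
) -> float:
    """Qualifying (in-series) movements per hour of the collection."""
    if sleep_hours <= 0:
        raise ValueError("sleep_hours must be > 0")
    return len(qualifying_events(events, params)) / sleep_hours


def has_plms_disorder(index: float) -> bool:
    """True iff the PLMS index is 5 or more per hour."""
    if index < 0:
        raise ValueError("PLMS index cannot be negative")
    return index >= PLMS_DISORDER_THRESHOLD


def angle_difference_trend(gyro: np.ndarray, rate: float = 100.0) -> float:
    """Slope of the cumulative integrated angular change across a window,
    expressed in degrees per window.

    The gyroscope norm (deg/s) is integrated into cumulative angular change;
    the least-squares slope of that curve (deg/s) times the window span gives
    a per-window trend whose sign is carried by the dominant rotation axis.
    """
    g = np.asarray(gyro, dtype=float)
    if g.size == 0 or g.shape[0] < 2:
        return 0.0
    # signed speed along the dominant axis, so direction is preserved
    dominant = int(np.argmax(np.abs(g).sum(axis=0)))
    speed = g[:, dominant]
    angle = np.cumsum(speed) / rate  # deg
    t = np.arange(angle.size) / rate
    slope = np.polyfit(t, angle, 1)[0]  # deg/s
    return float(slope * (angle.size / rate))
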