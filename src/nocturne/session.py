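"""Per-night sensor sessions: data model, file I/O, windowing, wet-moment detection.

A night of home monitoring is a set of aligned channel streams:

==========  =======  ==========================================
channel     rate     samples
==========  =======  ==========================================
bi          250 Hz   bioimpedance near the pelvis, ohm
moisture    250 Hz   moisture-sensor resistance, ohm
beats       event    R-peak (heartbeat) times, seconds
accel_l/r   100 Hz   3-axis ankle acceleration, g
gyro_l/r    100 Hz   3-axis ankle angular velocity, deg/s
ecg         250 Hz   optional raw ECG (only in raw-ECG mode)
==========  =======  ==========================================

All times are seconds from collection start.  Downstream analysis operates
on non-overlapping, contiguous 30-s windows indexed from 0, each covering
the half-open span ``[30*i, 30*(i+1))``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "ChannelStream",
    "SensorNight",
    "WindowGrid",
    "SessionError",
    "read_night",
    "write_night",
    "resample_and_align",
    "detect_wet_moment",
    "WINDOW_LENGTH",
    "CHANNEL_RATES",
]

WINDOW_LENGTH = 30.0

#: declared sampling rate per channel name; ``beats`` is an event stream.
CHANNEL_RATES = {
    "bi": 250.0,
    "moisture": 250.0,
    "ecg": 250.0,
    "beats": None,
    "accel_l": 100.0,
    "accel_r": 100.0,
    "gyro_l": 100.0,
    "gyro_r": 100.0,
}

_VECTOR_CHANNELS = {"accel_l", "accel_r", "gyro_l", "gyro_r"}


class SessionError(ValueError):
    """Malformed session data (bad channel, length mismatch, parse failure)."""


@dataclass
class ChannelStream:
    """One sensor channel: a uniformly sampled series or an event-time series."""

    name: str
    rate: float | None
    start_time: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        if self.name not in CHANNEL_RATES:
            raise SessionError(f"unknown channel name {self.name!r}")
        declared = CHANNEL_RATES[self.name]
        if declared is None:
            self.rate = None
        elif self.rate != declared:
            raise SessionError(
                f"channel {self.name!r} declared at {declared} Hz, got {self.rate}"
            )
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.name in _VECTOR_CHANNELS:
            if self.samples.ndim != 2 or self.samples.shape[1] != 3:
                raise SessionError(
                    f"channel {self.name!r} must be (n, 3); got {self.samples.shape}"
                )
        elif self.samples.ndim != 1:
            raise SessionError(f"channel {self.name!r} must be 1-D")

    @property
    def duration(self) -> float:
        if self.rate is None:
            return float(self.samples[-1]) if self.samples.size else 0.0
        return self.samples.shape[0] / self.rate

    def times(self) -> np.ndarray:
        """Sample times in seconds from collection start."""
        if self.rate is None:
            return self.samples
        n = self.samples.shape[0]
        return self.start_time + np.arange(n) / self.rate

    def validate_span(self, span: float) -> None:
        """Check sample count is consistent with ``span`` at this rate (±1 sample)."""
        if self.rate is None:
            if self.samples.size and self.samples[-1] > span + 1e-9:
                raise SessionError(
                    f"channel {self.name!r}: event at {self.samples[-1]:.3f}s "
                    f"beyond span {span:.3f}s"
                )
            return
        expected = span * self.rate
        if abs(self.samples.shape[0] - expected) > 1.0 + 1e-9:
            raise SessionError(
                f"channel {self.name!r}: {self.samples.shape[0]} samples, "
                f"expected {expected:.1f} (±1) for span {span:.1f}s at {self.rate} Hz"
            )


@dataclass
class SensorNight:
    """One night's aligned multi-channel streams plus metadata."""

    subject_id: str
    night_id: str
    channels: dict[str, ChannelStream]
    is_ne_day: bool
    ne_moment: float | None
    collection_span: float

    def __post_init__(self) -> None:
        if self.is_ne_day != (self.ne_moment is not None):
            raise SessionError("is_ne_day must hold exactly when ne_moment is present")
        if self.ne_moment is not None and not (0 <= self.ne_moment <= self.collection_span):
            raise SessionError(
                f"ne_moment {self.ne_moment} outside collection span "
                f"[0, {self.collection_span}]"
            )
        for ch in self.channels.values():
            ch.validate_span(self.collection_span)

    def channel(self, name: str) -> ChannelStream:
        try:
            return self.channels[name]
        except KeyError:
            raise SessionError(f"night {self.night_id!r} is missing channel {name!r}") from None


@dataclass
class WindowGrid:
    """Per-channel sample views aligned to a common 30-s window clock.

    ``bi``/``moisture`` retain full 30-s sub-series per window (bladder features
    need sample-level successive differences); ``beats`` holds event times per
    window; motion channels hold (n, 3) sub-series per window.  ``missing``
    flags windows invalidated by long dropouts in the bi channel.
    """

    window_length: float
    n_windows: int
    night: SensorNight
    bi: list[np.ndarray]
    moisture: list[np.ndarray] | None
    beats: list[np.ndarray] | None
    motion: dict[str, list[np.ndarray]]
    missing: np.ndarray  # bool per window

    @property
    def window_starts(self) -> np.ndarray:
        return np.arange(self.n_windows) * self.window_length

    @property
    def window_ends(self) -> np.ndarray:
        return (np.arange(self.n_windows) + 1) * self.window_length

    def __len__(self) -> int:
        return self.n_windows


def _interpolate_gaps(x: np.ndarray, rate: float, gap_limit: float) -> tuple[np.ndarray, np.ndarray]:
    """Linearly fill NaN runs no longer than ``gap_limit`` seconds.

    Returns the filled series and a boolean mask of samples still missing
    (runs longer than the limit, or runs touching either end).
    """
    x = x.copy()
    isnan = np.isnan(x)
    if not isnan.any():
        return x, isnan
    max_len = int(round(gap_limit * rate))
    # locate NaN runs
    edges = np.diff(np.concatenate(([0], isnan.view(np.int8), [0])))
    starts = np.flatnonzero(edges == 1)
    stops = np.flatnonzero(edges == -1)
    still_missing = np.zeros_like(isnan)
    idx = np.arange(x.size)
    for a, b in zip(starts, stops):
        run = b - a
        if run <= max_len and a > 0 and b < x.size:
            x[a:b] = np.interp(idx[a:b], [a - 1, b], [x[a - 1], x[b]])
        else:
            still_missing[a:b] = True
            x[a:b] = np.nan
    return x, still_missing


def resample_and_align(
    night: SensorNight,
    window_length: float = WINDOW_LENGTH,
    gap_limit: float = 10.0,
) -> WindowGrid:
    """Interpolate short dropouts and synchronize all channels onto 30-s windows.

    Gaps (NaN runs) shorter than ``gap_limit`` seconds in the bi/moisture
    channels are linearly interpolated between their endpoints; windows
    touched by longer gaps are flagged missing and excluded downstream.

    Raises
    ------
    SessionError
        If the bi channel is absent or the night is shorter than one window.
    """
    bi = night.channel("bi")
    n_windows = int(np.floor(night.collection_span / window_length))
    if n_windows < 1:
        raise SessionError(
            f"night span {night.collection_span:.1f}s is shorter than one "
            f"{window_length:.0f}s window"
        )
    missing = np.zeros(n_windows, dtype=bool)

    def split_dense(ch: ChannelStream) -> tuple[list[np.ndarray], np.ndarray]:
        filled, bad = _interpolate_gaps(ch.samples, ch.rate, gap_limit)
        per = int(round(window_length * ch.rate))
        win_bad = np.zeros(n_windows, dtype=bool)
        out = []
        for i in range(n_windows):
            seg = filled[i * per : (i + 1) * per]
            out.append(seg)
            if bad[i * per : (i + 1) * per].any():
                win_bad[i] = True
        return out, win_bad

    bi_windows, bi_bad = split_dense(bi)
    missing |= bi_bad

    moisture_windows = None
    if "moisture" in night.channels:
        moisture_windows, _ = split_dense(night.channels["moisture"])

    beat_windows = None
    if "beats" in night.channels:
        t = night.channels["beats"].samples
        beat_windows = [
            t[(t >= i * window_length) & (t < (i + 1) * window_length)]
            for i in range(n_windows)
        ]

    motion: dict[str, list[np.ndarray]] = {}
    for name in ("accel_l", "accel_r", "gyro_l", "gyro_r"):
        if name in night.channels:
            ch = night.channels[name]
            per = int(round(window_length * ch.rate))
            motion[name] = [ch.samples[i * per : (i + 1) * per] for i in range(n_windows)]

    return WindowGrid(
        window_length=window_length,
        n_windows=n_windows,
        night=night,
        bi=bi_windows,
        moisture=moisture_windows,
        beats=beat_windows,
        motion=motion,
        missing=missing,
    )


def detect_wet_moment(
    moisture: ChannelStream,
    threshold_fraction: float = 0.5,
    smooth_seconds: float = 1.0,
    baseline_seconds: float = 300.0,
) -> float | None:
    """First time the smoothed moisture resistance drops below a fraction of
    the dry baseline; ``None`` if the night stays dry.

    The resistance is median-smoothed over ``smooth_seconds``; the dry
    baseline is the median over the first ``baseline_seconds`` (collection
    always starts dry).  A drop too close to the end of the stream to be
    median-confirmed is still reported at the start of the trailing
    below-threshold run.
    """
    if moisture.rate is None:
        raise SessionError("moisture must be a uniformly sampled channel")
    x = moisture.samples
    rate = moisture.rate
    n_base = max(1, min(x.size, int(round(baseline_seconds * rate))))
    baseline = float(np.nanmedian(x[:n_base]))
    threshold = threshold_fraction * baseline

    w = max(1, int(round(smooth_seconds * rate)))
    smoothed = (
        pd.Series(x).rolling(window=w, min_periods=max(1, w // 2), center=True).median().to_numpy()
    )
    below = smoothed < threshold
    idx = np.flatnonzero(below)
    if idx.size:
        return float(idx[0] / rate)
    # boundary case: a sharp drop within the last half-smoothing-window cannot
    # be median-confirmed; report the trailing raw below-threshold run instead.
    raw_below = x < threshold
    if raw_below.size and raw_below[-1]:
        last_dry = np.flatnonzero(~raw_below)
        start = int(last_dry[-1]) + 1 if last_dry.size else 0
        return float(start / rate)
    return None


# ---------------------------------------------------------------------------
# file formats
#
# Format A: a directory with one CSV per channel plus metadata.json
#   bi.csv / moisture.csv / ecg.csv : columns time,value
#   beats.csv                       : column time
#   accel_l.csv etc.                : columns time,x,y,z
# Format B: one HDF5 file, one dataset per channel (named as the channel),
#   metadata stored as root attributes (ne_moment attr absent on dry nights).
# ---------------------------------------------------------------------------


def write_night(night: SensorNight, path: str | Path) -> Path:
    """Write a night in Format A (directory of CSVs) or Format B (``.h5``/``.hdf5``)."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        return _write_hdf5(night, path)
    return _write_csv_dir(night, path)


def read_night(path: str | Path) -> SensorNight:
    """Read a night written by :func:`write_night` (either format)."""
    path = Path(path)
    if path.is_file() and path.suffix.lower() in (".h5", ".hdf5"):
        return _read_hdf5(path)
    if path.is_dir():
        return _read_csv_dir(path)
    raise SessionError(f"{path} is neither an HDF5 file nor a session directory")


def _metadata(night: SensorNight) -> dict:
    return {
        "subject_id": night.subject_id,
        "night_id": night.night_id,
        "is_ne_day": bool(night.is_ne_day),
        "ne_moment": night.ne_moment,
        "collection_span": night.collection_span,
    }


def _write_csv_dir(night: SensorNight, path: Path) -> Path:
    path.mkdir(parents=True, exist_ok=True)
    (path / "metadata.json").write_text(json.dumps(_metadata(night), indent=1))
    for name, ch in night.channels.items():
        f = path / f"{name}.csv"
        t = ch.times()
        if name == "beats":
            pd.DataFrame({"time": t}).to_csv(f, index=False)
        elif name in _VECTOR_CHANNELS:
            pd.DataFrame(
                {"time": t, "x": ch.samples[:, 0], "y": ch.samples[:, 1], "z": ch.samples[:, 2]}
            ).to_csv(f, index=False)
        else:
            pd.DataFrame({"time": t, "value": ch.samples}).to_csv(f, index=False)
    return path


def _read_csv_dir(path: Path) -> SensorNight:
    meta_path = path / "metadata.json"
    if not meta_path.exists():
        raise SessionError(f"{path} has no metadata.json")
    meta = json.loads(meta_path.read_text())
    channels: dict[str, ChannelStream] = {}
    for f in sorted(path.glob("*.csv")):
        name = f.stem
        if name not in CHANNEL_RATES:
            continue
        try:
            df = pd.read_csv(f)
        except Exception as exc:  # noqa: BLE001 - rewrap with channel context
            raise SessionError(f"channel {name!r}: failed to parse {f}: {exc}") from exc
        if name == "beats":
            samples = df["time"].to_numpy(dtype=np.float64)
            start = 0.0
        elif name in _VECTOR_CHANNELS:
            _require_columns(df, ("time", "x", "y", "z"), name)
            samples = df[["x", "y", "z"]].to_numpy(dtype=np.float64)
            start = float(df["time"].iloc[0]) if len(df) else 0.0
        else:
            _require_columns(df, ("time", "value"), name)
            samples = df["value"].to_numpy(dtype=np.float64)
            start = float(df["time"].iloc[0]) if len(df) else 0.0
        channels[name] = ChannelStream(
            name=name, rate=CHANNEL_RATES[name], start_time=start, samples=samples
        )
    if "bi" not in channels:
        raise SessionError(f"{path} is missing the required 'bi' channel file")
    return SensorNight(
        subject_id=meta["subject_id"],
        night_id=meta["night_id"],
        channels=channels,
        is_ne_day=meta["is_ne_day"],
        ne_moment=meta["ne_moment"],
        collection_span=meta["collection_span"],
    )


def _require_columns(df: pd.DataFrame, cols: tuple[str, ...], name: str) -> None:
    for c in cols:
        if c not in df.columns:
            raise SessionError(f"channel {name!r}: missing column {c!r}")


def _write_hdf5(night: SensorNight, path: Path) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as h5:
        for k, v in _metadata(night).items():
            if v is not None:
                h5.attrs[k] = v
        for name, ch in night.channels.items():
            ds = h5.create_dataset(name, data=ch.samples)
            ds.attrs["start_time"] = ch.start_time
            if ch.rate is not None:
                ds.attrs["rate"] = ch.rate
    return path


def _read_hdf5(path: Path) -> SensorNight:
    channels: dict[str, ChannelStream] = {}
    with h5py.File(path, "r") as h5:
        meta = dict(h5.attrs)
        for name in h5:
            if name not in CHANNEL_RATES:
                raise SessionError(f"{path}: unknown channel dataset {name!r}")
            ds = h5[name]
            channels[name] = ChannelStream(
                name=name,
                rate=CHANNEL_RATES[name],
                start_time=float(ds.attrs.get("start_time", 0.0)),
                samples=ds[...],
            )
    if "bi" not in channels:
        raise SessionError(f"{path} is missing the required 'bi' channel dataset")
    ne_moment = meta.get("ne_moment")
    return SensorNight(
        subject_id=str(meta["subject_id"]),
        night_id=str(meta["night_id"]),
        channels=channels,
        is_ne_day=bool(meta["is_ne_day"]),
        ne_moment=float(ne_moment) if ne_moment is not None else None,
        collection_span=float(meta["collection_span"]),
    )
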