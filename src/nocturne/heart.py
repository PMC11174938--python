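"""Heartbeat intervals and windowed heart-rate-variability features.

Beat (R-peak) times come either directly from the device pipeline or from
R-peak detection on a raw ECG.  Successive beat times give NN intervals in
milliseconds, gated to a physiologic range; each 30-s window yields nine
features: HR max/mean/min/std (from instantaneous per-interval rates,
60000/NN), the counts nni_20/nni_50 of absolute successive-interval
differences exceeding 20/50 ms, their percentages pnni_20/pnni_50, and
range_nn = max - min interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "NNSeries",
    "HRV_FEATURES",
    "detect_r_peaks",
    "nn_intervals",
    "hrv_window_features",
]

#: FeatureFrame column names, in order.
HRV_FEATURES = (
    "hr_max", "hr_mean", "hr_min", "hr_std",
    "nni_20", "nni_50", "pnni_20", "pnni_50", "range_nn",
)

#: physiologic NN gate in ms (covers pediatric sleep heart rates)
NN_GATE_MS = (300.0, 2000.0)


@dataclass
class NNSeries:
    """Gated NN intervals (ms) and the beat times that ended each interval."""

    intervals: np.ndarray
    beat_times: np.ndarray

    def __len__(self) -> int:
        return self.intervals.size


def detect_r_peaks(ecg: np.ndarray, rate: float = 250.0) -> np.ndarray:
    """R-peak times (s) from a raw ECG via band-pass + prominence peak picking.

    Returns an empty array (with a warning) on a flat signal.
    """
    ecg = np.asarray(ecg, dtype=float)
    if ecg.size < int(rate):
        return np.empty(0)
    if np.ptp(ecg) < 1e-12:
        warnings.warn("flat ECG signal: no R-peaks detected", stacklevel=2)
        return np.empty(0)
    # QRS energy lives roughly in 5-40 Hz
    sos = signal.butter(3, [5.0, 40.0], btype="bandpass", fs=rate, output="sos")
    filt = signal.sosfiltfilt(sos, ecg)
    mad = np.median(np.abs(filt - np.median(filt)))
    if mad < 1e-12:
        warnings.warn("flat ECG signal after filtering: no R-peaks detected", stacklevel=2)
        return np.empty(0)
    height = 4.0 * 1.4826 * mad
    min_dist = int(0.3 * rate)  # refractory: no two beats within 300 ms
    peaks, _ = signal.find_peaks(filt, height=height, distance=min_dist)
    if peaks.size == 0:
        return np.empty(0)
    # refine each peak to the raw-signal maximum in a small neighbourhood
    half = max(1, int(0.03 * rate))
    refined = np.array(
        [max(0, p - half) + np.argmax(ecg[max(0, p - half): p + half + 1]) for p in peaks]
    )
    return np.unique(refined) / rate


def nn_intervals(
    beat_times: np.ndarray,
    gate_ms: tuple[float, float] = NN_GATE_MS,
) -> NNSeries:
    """Successive beat-time differences in ms, outside-gate intervals removed."""
    t = np.sort(np.asarray(beat_times, dtype=float))
    if t.size < 2:
        return NNSeries(intervals=np.empty(0), beat_times=np.empty(0))
    nn = np.diff(t) * 1000.0
    keep = (nn >= gate_ms[0]) & (nn <= gate_ms[1])
    return NNSeries(intervals=nn[keep], beat_times=t[1:][keep])


def hrv_window_features(nn: NNSeries) -> dict[str, float] | None:
    """The nine windowed HRV features; ``None`` if the window has < 2 intervals
    (the caller flags the window missing rather than raising)."""
    x = nn.intervals
    if x.size < 2:
        return None
    inst_hr = 60000.0 / x
    d = np.abs(np.diff(x))
    n_d = d.size
    nni_20 = int(np.count_nonzero(d > 20.0))
    nni_50 = int(np.count_nonzero(d > 50.0))
    return {
        "hr_max": float(inst_hr.max()),
        "hr_mean": float(inst_hr.mean()),
        "hr_min": float(inst_hr.min()),
        "hr_std": float(inst_hr.std(ddof=0)),
        "nni_20": nni_20,
        "nni_50": nni_50,
        "pnni_20": 100.0 * nni_20 / n_d,
        "pnni_50": 100.0 * nni_50 / n_d,
        "range_nn": float(x.max() - x.min()),
    }
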