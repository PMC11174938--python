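"""Cohort analyses: event-driven and sequential summaries, correlations.

Enuresis data can be read two ways.  *Event-driven*: compare feature
distributions at anchor points of each night (start, middle, end) — natural
when the phenomenon is organized around the wetting event.  *Sequential*:
map every night onto normalized time [0, 1] and aggregate per time bin —
natural when the overnight trajectory matters.  Both are computed separately
for enuretic and dry nights.

The saline-filling correlation study asks whether the designed bioimpedance
features track injected bladder volume better than raw bioimpedance does;
:func:`uds_feature_correlations` reports per-session and pooled Pearson
correlations (signed and absolute — the appropriate sign convention for a
feature that *falls* with volume is ambiguous, so both are given).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import bladder
from .simulate import UDSRecord

__all__ = [
    "AnchorSummary",
    "SequentialSummary",
    "event_driven_summary",
    "sequential_summary",
    "pearson",
    "uds_feature_correlations",
    "hr_rise_before_ne",
]

log = logging.getLogger(__name__)

_ANCHORS = ("start", "middle", "end")


@dataclass
class AnchorSummary:
    """Per-night anchor means and their cohort distribution for one stratum."""

    feature: str
    anchor: str
    stratum: str                 # "ne" | "dry"
    per_night: np.ndarray        # mean of the k anchor windows, one per night
    median: float
    iqr: tuple[float, float]


@dataclass
class SequentialSummary:
    """Cohort statistics over normalized night time for one stratum."""

    feature: str
    stratum: str
    bin_edges: np.ndarray        # n_bins + 1 edges partitioning [0, 1]
    bin_median: np.ndarray
    bin_iqr: np.ndarray          # (n_bins, 2)
    bin_mean: np.ndarray


def _stratum(frame: pd.DataFrame) -> str:
    return "ne" if frame.attrs.get("is_ne_day") else "dry"


def _anchor_values(values: np.ndarray, k: int) -> dict[str, float]:
    n = values.size
    mid = n // 2
    half = k // 2
    return {
        "start": float(np.nanmean(values[:k])),
        "middle": float(np.nanmean(values[max(0, mid - half): max(0, mid - half) + k])),
        "end": float(np.nanmean(values[-k:])),
    }


def event_driven_summary(
    frames: list[pd.DataFrame], feature: str, k_windows: int = 10
) -> dict[tuple[str, str], AnchorSummary]:
    """Anchor summaries keyed ``(stratum, anchor)``.

    Each night contributes the mean of its first ``k_windows`` windows
    (start), ``k_windows`` centred at n/2 (middle), and its last
    ``k_windows`` (end).  Nights shorter than ``3 * k_windows`` windows are
    excluded with a log entry.
    """
    if k_windows < 1:
        raise ValueError("k_windows must be >= 1")
    per: dict[tuple[str, str], list[float]] = {}
    for frame in frames:
        valid = frame.loc[~frame["missing"], feature].to_numpy()
        if valid.size < 3 * k_windows:
            log.info(
                "night %s excluded from event-driven summary: %d valid windows < %d",
                frame.attrs.get("night_id"), valid.size, 3 * k_windows,
            )
            continue
        s = _stratum(frame)
        for anchor, v in _anchor_values(valid, k_windows).items():
            per.setdefault((s, anchor), []).append(v)
    out = {}
    for (s, anchor), vals in per.items():
        arr = np.asarray(vals)
        out[(s, anchor)] = AnchorSummary(
            feature=feature,
            anchor=anchor,
            stratum=s,
            per_night=arr,
            median=float(np.median(arr)),
            iqr=(float(np.percentile(arr, 25)), float(np.percentile(arr, 75))),
        )
    return out


def sequential_summary(
    frames: list[pd.DataFrame], feature: str, n_bins: int = 10
) -> dict[str, SequentialSummary]:
    """Per-stratum profiles over normalized night time, keyed by stratum.

    Each night's windows are mapped to ``t / t_end`` and pooled into
    ``n_bins`` equal bins of [0, 1].
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    pooled: dict[str, list[list[float]]] = {}
    for frame in frames:
        sub = frame.loc[~frame["missing"], ["time", feature]].dropna()
        if sub.empty:
            continue
        t_norm = sub["time"].to_numpy() / frame["time"].iloc[-1]
        which = np.clip(np.digitize(t_norm, edges) - 1, 0, n_bins - 1)
        bins = pooled.setdefault(_stratum(frame), [[] for _ in range(n_bins)])
        for b, v in zip(which, sub[feature].to_numpy()):
            bins[b].append(v)
    out = {}
    for s, bins in pooled.items():
        med = np.array([np.median(b) if b else np.nan for b in bins])
        mean = np.array([np.mean(b) if b else np.nan for b in bins])
        iqr = np.array(
            [
                (np.percentile(b, 25), np.percentile(b, 75)) if b else (np.nan, np.nan)
                for b in bins
            ]
        )
        out[s] = SequentialSummary(
            feature=feature, stratum=s, bin_edges=edges,
            bin_median=med, bin_iqr=iqr, bin_mean=mean,
        )
    return out


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson correlation with its two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("pearson needs two equal-length series of length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("pearson requires finite values")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError("correlation undefined for a zero-variance series")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def uds_feature_correlations(
    sessions: list[UDSRecord],
    params: bladder.BVParams = bladder.BVParams(),
    window_length: float = 30.0,
) -> pd.DataFrame:
    """Correlation of raw BI and each designed BI feature with injected volume.

    Every session is windowed at ``window_length`` s; per window we take the
    raw-BI mean, the designed features, and the injected volume at the window
    end, then correlate feature against volume per session and pooled over
    sessions.  Returns a table with columns ``feature, scope, r_signed,
    r_abs, p`` where scope is ``per_session_mean`` or ``pooled``.  Degenerate
    sessions (too short, zero variance) are excluded with a log entry.
    """
    if len(sessions) < 3:
        raise ValueError("need at least 3 sessions")
    feature_names = ("BI_raw", "BID", "BID_decrease", "DBID", "Clt")
    per_session: dict[str, list[float]] = {f: [] for f in feature_names}
    pooled_x: dict[str, list[np.ndarray]] = {f: [] for f in feature_names}
    pooled_v: list[np.ndarray] = []

    for idx, s in enumerate(sessions):
        per = int(round(window_length * s.bi_rate))
        n_windows = s.bi_stream.size // per
        if n_windows < 3:
            log.info("session %d excluded: only %d windows", idx, n_windows)
            continue
        windows = [s.bi_stream[i * per : (i + 1) * per] for i in range(n_windows)]
        feats = bladder.window_bi_features(windows, s.bi_rate, params)
        t_ends = (np.arange(n_windows) + 1) * window_length
        vol = np.interp(
            t_ends, np.arange(s.injected_volume.size) / s.volume_rate, s.injected_volume
        )
        cols = {
            "BI_raw": np.array([w.mean() for w in windows]),
            "BID": feats["BID"],
            "BID_decrease": feats["BID_decrease"],
            "DBID": feats["DBID"],
            "Clt": feats["Clt"],
        }
        if np.std(vol) == 0.0:
            log.info("session %d excluded: constant volume", idx)
            continue
        for f, x in cols.items():
            ok = np.isfinite(x)
            if ok.sum() >= 3 and np.std(x[ok]) > 0:
                r, _ = pearson(x[ok], vol[ok])
                per_session[f].append(r)
            pooled_x[f].append(x)
        pooled_v.append(vol)

    rows = []
    for f in ("BI_raw", "BID", "BID_decrease", "DBID", "Clt"):
        rs = np.asarray(per_session[f])
        if rs.size:
            rows.append(
                dict(feature=f, scope="per_session_mean",
                     r_signed=float(rs.mean()), r_abs=float(np.abs(rs).mean()), p=np.nan)
            )
        x = np.concatenate(pooled_x[f])
        v = np.concatenate(pooled_v)
        ok = np.isfinite(x)
        if ok.sum() >= 3 and np.std(x[ok]) > 0:
            r, p = pearson(x[ok], v[ok])
            rows.append(
                dict(feature=f, scope="pooled", r_signed=r, r_abs=abs(r), p=p)
            )
    return pd.DataFrame(rows)


def hr_rise_before_ne(
    frame: pd.DataFrame,
    threshold_bpm: float = 3.0,
    span_seconds: float = 300.0,
    baseline_guard_seconds: float = 600.0,
    baseline_span_seconds: float = 1200.0,
) -> bool:
    """Did the heart rate rise before the wetting moment on this night?

    Compares the mean windowed heart rate over the ``span_seconds``
    immediately before the wetting moment against a *local* baseline taken
    just before any plausible pre-wetting ramp — the ``baseline_span_seconds``
    ending ``baseline_guard_seconds`` before the wetting moment.  A nearby
    baseline cancels the night's slow heart-rate wander, which a
    start-of-night baseline would not.  Falls back to the night's opening
    ``span_seconds`` when the wetting moment is too early for a local
    baseline.  Flags a rise when the difference exceeds ``threshold_bpm``.
    """
    ne_moment = frame.attrs.get("ne_moment")
    if ne_moment is None:
        raise ValueError("hr_rise_before_ne requires an enuretic night")
    valid = frame.loc[~frame["missing"]]
    pre = valid.loc[
        (valid["time"] > ne_moment - span_seconds) & (valid["time"] <= ne_moment),
        "hr_mean",
    ]
    base_hi = ne_moment - baseline_guard_seconds
    base = valid.loc[
        (valid["time"] > base_hi - baseline_span_seconds) & (valid["time"] <= base_hi),
        "hr_mean",
    ]
    if base.empty:
        base = valid.loc[valid["time"] <= span_seconds, "hr_mean"]
    if base.empty or pre.empty:
        return False
    return bool(pre.mean() - base.mean() > threshold_bpm)
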