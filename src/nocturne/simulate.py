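"""Synthetic multi-sensor nights and saline-filling sessions with planted ground truth.

The real cohort behind this pipeline (four children monitored at home over an
eight-week alarm-treatment course, plus thirty children in a one-time
in-hospital urodynamic study) cannot be redistributed, so every downstream
stage is exercised on simulated nights instead.  The generator emulates the
statistical structure the pipeline consumes:

* per-subject bioimpedance (BI) baseline offsets and posture step-changes;
* a slow BI decrease as the bladder fills (urine conducts, so impedance near
  the pelvis falls with bladder volume);
* large short movement-artifact excursions in BI;
* heartbeat (R-peak) times with a configurable pre-wetting heart-rate ramp on
  a fraction of enuretic nights;
* periodic-limb-movement burst series on both ankles with AASM-style
  geometry (series of >= 4 movements, 5-90 s apart, 0.5-10 s long);
* a moisture-sensor resistance drop at the wetting moment.

Defaults mirror the monitored cohort where its summary statistics are known:
~45% of nights enuretic (78 of 173), a pre-wetting heart-rate rise on ~29%
of enuretic nights (23 of 78), and a periodic-limb-movement index near the
cohort mean of 15.59 events/hour.

Determinism: every night is generated from ``SeedSequence(seed, night_index)``,
so identical ``(seed, night_index)`` pairs give bit-identical streams and
cohorts can be regenerated night-by-night.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .session import ChannelStream, SensorNight

__all__ = [
    "SimConfig",
    "SimulatedNight",
    "UDSRecord",
    "ConfigError",
    "simulate_night",
    "simulate_cohort",
    "simulate_uds_session",
    "synthetic_ecg",
]


class ConfigError(ValueError):
    """Invalid simulator configuration; the message names the offending field."""


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters. Units are in field names or noted here.

    ``*_ne`` overrides apply to enuretic nights only; ``None`` means "same as
    the dry-night value" — they exist so strongly separable cohorts (steeper
    filling, denser limb movements on wet nights) can be generated for
    estimator benchmarks.
    """

    seed: int = 0
    n_nights: int = 1
    ne_fraction: float = 78 / 173          # fraction of nights enuretic
    sleep_duration: float = 8 * 3600.0     # s
    bi_rate: float = 250.0                 # Hz
    motion_rate: float = 100.0             # Hz
    bi_baseline_range: tuple[float, float] = (150.0, 450.0)  # ohm, per subject
    bi_fill_slope: float = -6.0            # ohm/hour; negative = filling lowers BI
    bi_fill_slope_ne: float | None = None  # override on enuretic nights
    bi_noise_sd: float = 0.3               # ohm, SD of the band-limited BI noise
    bi_noise_knot_seconds: float = 30.0    # correlation scale of the BI noise
    posture_shift_rate: float = 1.5        # events/hour
    posture_step_magnitude: float = 4.0    # ohm, |step| near the clipping bound
    artifact_rate: float = 6.0             # events/hour
    artifact_magnitude: float = 40.0       # ohm, |spike offset| >> clipping bound
    artifact_duration: tuple[float, float] = (0.5, 3.0)  # s
    hr_baseline: float = 85.0              # bpm
    hr_slow_sd: float = 1.5                # bpm, slow overnight wander
    hr_jitter_ms: float = 25.0             # beat-to-beat interval jitter
    hr_ramp_probability: float = 23 / 78   # fraction of enuretic nights ramped
    hr_ramp_magnitude: float = 8.0         # bpm rise before the wetting moment
    hr_ramp_duration: float = 600.0        # s of pre-wetting ramp
    plm_index_target: float = 15.59        # in-series limb movements / hour
    plm_index_target_ne: float | None = None
    plm_series_length: tuple[int, int] = (4, 8)       # movements per series
    plm_inter_onset: tuple[float, float] = (10.0, 60.0)  # s, within [5, 90]
    plm_duration: tuple[float, float] = (0.5, 4.0)    # s, within [0.5, 10]
    lm_isolated_rate: float = 3.0          # non-series movements / hour
    lm_amplitude: float = 0.4              # g, accel burst amplitude
    gyro_amplitude: float = 60.0           # deg/s, gyro burst amplitude
    accel_noise_sd: float = 0.01           # g
    gyro_noise_sd: float = 1.0             # deg/s
    moisture_dry_level: float = 10_000.0   # ohm
    moisture_wet_level: float = 300.0      # ohm
    moisture_noise_sd: float = 50.0        # ohm
    ne_window: tuple[float, float] = (0.3, 1.0)  # wetting uniform in this night fraction
    raw_ecg: bool = False                  # also emit a raw ECG waveform channel
    uds_slope_per_cc: float = -0.08        # ohm per cc of injected saline

    def __post_init__(self) -> None:
        def check(cond: bool, name: str, why: str) -> None:
            if not cond:
                raise ConfigError(f"{name}: {why}")

        check(self.n_nights >= 0, "n_nights", "must be >= 0")
        check(0.0 <= self.ne_fraction <= 1.0, "ne_fraction", "must be in [0, 1]")
        check(0.0 <= self.hr_ramp_probability <= 1.0, "hr_ramp_probability", "must be in [0, 1]")
        check(self.sleep_duration > 0, "sleep_duration", "must be > 0")
        check(self.bi_rate > 0, "bi_rate", "must be > 0")
        check(self.motion_rate > 0, "motion_rate", "must be > 0")
        check(
            self.bi_baseline_range[0] <= self.bi_baseline_range[1],
            "bi_baseline_range", "must be a non-empty interval",
        )
        check(
            self.moisture_wet_level < self.moisture_dry_level,
            "moisture_wet_level", "must be below moisture_dry_level",
        )
        check(self.plm_series_length[0] >= 4, "plm_series_length", "series need >= 4 movements")
        check(
            5.0 <= self.plm_inter_onset[0] <= self.plm_inter_onset[1] <= 90.0,
            "plm_inter_onset", "must lie within [5, 90] s",
        )
        check(
            0.5 <= self.plm_duration[0] <= self.plm_duration[1] <= 10.0,
            "plm_duration", "must lie within [0.5, 10] s",
        )
        check(self.plm_index_target >= 0, "plm_index_target", "must be >= 0")
        check(
            0.0 <= self.ne_window[0] < self.ne_window[1] <= 1.0,
            "ne_window", "must be a sub-interval of [0, 1]",
        )


@dataclass
class LMGroundTruth:
    side: str
    onset: float
    duration: float
    in_series: bool


@dataclass
class SimulatedNight(SensorNight):
    """A :class:`~nocturne.session.SensorNight` plus planted ground truth."""

    true_ne_moment: float | None = None
    planted_lm_events: list[LMGroundTruth] = field(default_factory=list)
    hr_ramp_present: bool = False
    bi_drift_slope: float = 0.0  # ohm/hour actually planted


@dataclass
class UDSRecord:
    """A synthetic saline-filling (urodynamic) session.

    ``bi_stream`` is the 250 Hz pelvic bioimpedance during filling;
    ``injected_volume`` is the cumulative saline volume at 1 Hz, monotone
    non-decreasing from 0 to ``capacity`` (cc).
    """

    bi_stream: np.ndarray
    bi_rate: float
    injected_volume: np.ndarray
    volume_rate: float
    capacity: float

    @property
    def duration(self) -> float:
        return self.bi_stream.size / self.bi_rate


def _night_rng(config: SimConfig, night_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(night_index,)))


def _poisson_event_times(rng: np.random.Generator, rate_per_hour: float, span: float) -> np.ndarray:
    n = rng.poisson(rate_per_hour * span / 3600.0)
    return np.sort(rng.uniform(0.0, span, size=n))


def _burst_envelope(duration_samples: int) -> np.ndarray:
    # half-sine envelope: smooth on/offset, peak in the middle
    return np.sin(np.linspace(0.0, np.pi, duration_samples))


def _smooth_noise(
    rng: np.random.Generator, n: int, rate: float, sd: float, knot_seconds: float
) -> np.ndarray:
    """Band-limited Gaussian noise: knots every ``knot_seconds``, linearly
    interpolated.  Consecutive 4-ms samples of real bioimpedance hardware are
    strongly correlated; modelling the noise as smooth keeps sample-level
    successive differences dominated by real steps (posture, artifacts) and
    drift, which is what the cumulative-difference features rely on.
    """
    if sd <= 0 or n == 0:
        return np.zeros(n)
    n_knots = max(2, int(np.ceil(n / (knot_seconds * rate))) + 1)
    knots = rng.normal(0.0, sd, size=n_knots)
    knot_pos = np.linspace(0.0, n - 1, n_knots)
    return np.interp(np.arange(n), knot_pos, knots)


def simulate_night(config: SimConfig, night_index: int = 0) -> SimulatedNight:
    """Generate one synthetic night (deterministic in ``(seed, night_index)``)."""
    rng = _night_rng(config, night_index)
    span = config.sleep_duration
    is_ne = bool(rng.random() < config.ne_fraction)
    ne_moment = None
    if is_ne:
        lo, hi = config.ne_window
        ne_moment = float(rng.uniform(lo * span, hi * span))

    channels: dict[str, ChannelStream] = {}

    # --- bioimpedance -----------------------------------------------------
    n_bi = int(round(span * config.bi_rate))
    t_bi = np.arange(n_bi) / config.bi_rate
    baseline = rng.uniform(*config.bi_baseline_range)
    slope = config.bi_fill_slope
    if is_ne and config.bi_fill_slope_ne is not None:
        slope = config.bi_fill_slope_ne
    bi = baseline + slope * t_bi / 3600.0
    bi = bi + _smooth_noise(
        rng, n_bi, config.bi_rate, config.bi_noise_sd, config.bi_noise_knot_seconds
    )
    # posture step-changes: persistent baseline shifts of either sign
    for ts in _poisson_event_times(rng, config.posture_shift_rate, span):
        step = rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.5) * config.posture_step_magnitude
        bi[int(ts * config.bi_rate):] += step
    # movement artifacts: short large excursions, both edges exceed any
    # reasonable clipping bound
    for ts in _poisson_event_times(rng, config.artifact_rate, span):
        dur = rng.uniform(*config.artifact_duration)
        a = int(ts * config.bi_rate)
        b = min(n_bi, a + max(1, int(dur * config.bi_rate)))
        bi[a:b] += rng.choice([-1.0, 1.0]) * rng.uniform(1.0, 2.0) * config.artifact_magnitude
    channels["bi"] = ChannelStream("bi", config.bi_rate, 0.0, bi)

    # --- moisture ---------------------------------------------------------
    moist = np.full(n_bi, config.moisture_dry_level)
    if config.moisture_noise_sd > 0:
        moist = moist + rng.normal(0.0, config.moisture_noise_sd, size=n_bi)
    if is_ne:
        wet_from = int(ne_moment * config.bi_rate)
        moist[wet_from:] = config.moisture_wet_level + (
            rng.normal(0.0, config.moisture_noise_sd, size=n_bi - wet_from)
            if config.moisture_noise_sd > 0 else 0.0
        )
    channels["moisture"] = ChannelStream("moisture", config.bi_rate, 0.0, moist)

    # --- heartbeats -------------------------------------------------------
    hr_ramp_present = bool(is_ne and rng.random() < config.hr_ramp_probability)
    beats = _simulate_beats(rng, config, span, ne_moment if hr_ramp_present else None)
    channels["beats"] = ChannelStream("beats", None, 0.0, beats)
    if config.raw_ecg:
        ecg = synthetic_ecg(beats, span, config.bi_rate, rng)
        channels["ecg"] = ChannelStream("ecg", config.bi_rate, 0.0, ecg)

    # --- limb movements ---------------------------------------------------
    plm_target = config.plm_index_target
    if is_ne and config.plm_index_target_ne is not None:
        plm_target = config.plm_index_target_ne
    planted = _plan_limb_movements(rng, config, span, plm_target)
    for side, stream_name in (("left", "accel_l"), ("right", "accel_r")):
        events = [e for e in planted if e.side == side]
        accel, gyro = _render_motion(rng, config, span, events)
        channels[stream_name] = ChannelStream(stream_name, config.motion_rate, 0.0, accel)
        gname = "gyro_l" if side == "left" else "gyro_r"
        channels[gname] = ChannelStream(gname, config.motion_rate, 0.0, gyro)

    return SimulatedNight(
        subject_id=f"sim{config.seed}",
        night_id=f"night{night_index:04d}",
        channels=channels,
        is_ne_day=is_ne,
        ne_moment=ne_moment,
        collection_span=span,
        true_ne_moment=ne_moment,
        planted_lm_events=planted,
        hr_ramp_present=hr_ramp_present,
        bi_drift_slope=slope,
    )


def _simulate_beats(
    rng: np.random.Generator,
    config: SimConfig,
    span: float,
    ramp_until: float | None,
) -> np.ndarray:
    """Beat (R-peak) times from a slowly wandering instantaneous heart rate."""
    # slow wander: smooth random walk sampled per minute, interpolated
    n_knots = max(2, int(span / 60.0) + 1)
    knots = np.cumsum(rng.normal(0.0, config.hr_slow_sd / 4.0, size=n_knots))
    knots -= knots.mean()
    knots = np.clip(knots, -2.5 * config.hr_slow_sd, 2.5 * config.hr_slow_sd)
    knot_t = np.linspace(0.0, span, n_knots)

    def hr_at(t: float) -> float:
        hr = config.hr_baseline + np.interp(t, knot_t, knots)
        if ramp_until is not None:
            ramp_start = ramp_until - config.hr_ramp_duration
            if t >= ramp_until:
                hr += config.hr_ramp_magnitude
            elif t > ramp_start:
                hr += config.hr_ramp_magnitude * (t - ramp_start) / config.hr_ramp_duration
        return max(30.0, hr)

    beats = []
    t = float(rng.uniform(0.0, 0.5))
    while t < span:
        beats.append(t)
        interval = 60.0 / hr_at(t) + rng.normal(0.0, config.hr_jitter_ms / 1000.0)
        t += max(0.31, interval)  # stay above the 300 ms physiologic gate
    return np.asarray(beats)


def _plan_limb_movements(
    rng: np.random.Generator,
    config: SimConfig,
    span: float,
    plm_target: float,
) -> list[LMGroundTruth]:
    """Plant periodic-series and isolated limb-movement events.

    The number of in-series movements is Poisson with mean
    ``plm_target * hours``; movements are grouped into series with AASM-style
    geometry.  Isolated (non-qualifying) movements are planted far from any
    series so they can never merge into one.
    """
    hours = span / 3600.0
    events: list[LMGroundTruth] = []
    n_series_events = rng.poisson(plm_target * hours)

    occupied: list[tuple[float, float]] = []  # [start, end) spans of series
    min_len = config.plm_series_length[0]
    remaining = n_series_events
    if 0 < remaining < min_len:
        # too few for a qualifying series: plant a minimal series with
        # probability remaining/min_len so the expected count is preserved
        remaining = min_len if rng.random() < remaining / min_len else 0
    guard = 0
    while remaining >= min_len and guard < 1000:
        guard += 1
        length = int(rng.integers(min_len, config.plm_series_length[1] + 1))
        length = min(length, remaining)
        if remaining - length < min_len:
            length = remaining  # absorb the leftover into this series
        gaps = rng.uniform(*config.plm_inter_onset, size=length - 1)
        series_span = float(gaps.sum()) + config.plm_duration[1]
        if series_span >= span - 1.0:
            break
        start = float(rng.uniform(0.0, span - series_span - 1.0))
        lo, hi = start - 120.0, start + series_span + 120.0
        if any(not (hi < a or lo > b) for a, b in occupied):
            continue
        occupied.append((start, start + series_span))
        side = str(rng.choice(["left", "right"]))
        onset = start
        for k in range(length):
            dur = float(rng.uniform(*config.plm_duration))
            events.append(LMGroundTruth(side=side, onset=onset, duration=dur, in_series=True))
            if k < length - 1:
                onset += float(gaps[k])
        remaining -= length

    for ts in _poisson_event_times(rng, config.lm_isolated_rate, span - 15.0):
        lo, hi = ts - 120.0, ts + 120.0
        if any(not (hi < a or lo > b) for a, b in occupied):
            continue  # keep isolated events from joining a series
        side = str(rng.choice(["left", "right"]))
        dur = float(rng.uniform(*config.plm_duration))
        events.append(LMGroundTruth(side=side, onset=float(ts), duration=dur, in_series=False))
    events.sort(key=lambda e: e.onset)
    return events


def _render_motion(
    rng: np.random.Generator,
    config: SimConfig,
    span: float,
    events: list[LMGroundTruth],
) -> tuple[np.ndarray, np.ndarray]:
    """Render one ankle's 3-axis accelerometer (g) and gyroscope (deg/s)."""
    n = int(round(span * config.motion_rate))
    accel = rng.normal(0.0, config.accel_noise_sd, size=(n, 3))
    accel[:, 2] += 1.0  # gravity along z while lying still
    gyro = rng.normal(0.0, config.gyro_noise_sd, size=(n, 3))
    for e in events:
        a = int(e.onset * config.motion_rate)
        b = min(n, a + max(2, int(e.duration * config.motion_rate)))
        env = _burst_envelope(b - a)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        freq = rng.uniform(2.0, 6.0)  # Hz, jerk-like oscillation
        phase = rng.uniform(0.0, 2 * np.pi)
        carrier = np.sin(2 * np.pi * freq * np.arange(b - a) / config.motion_rate + phase)
        accel[a:b] += config.lm_amplitude * (env * carrier)[:, None] * direction[None, :]
        gdir = rng.normal(size=3)
        gdir /= np.linalg.norm(gdir)
        gyro[a:b] += config.gyro_amplitude * (env * carrier)[:, None] * gdir[None, :]
    return accel, gyro


def simulate_cohort(config: SimConfig) -> list[SimulatedNight]:
    """Generate ``config.n_nights`` nights, indexed 0..n_nights-1."""
    if config.n_nights < 1:
        raise ConfigError("n_nights: must be >= 1 to simulate a cohort")
    return [simulate_night(config, i) for i in range(config.n_nights)]


def simulate_balanced_cohort(config: SimConfig) -> list[SimulatedNight]:
    """A cohort with enuretic/dry nights forced to alternate (even indices
    enuretic).  Useful for estimator benchmarks where both classes must be
    present in any split; each night is otherwise identical to
    :func:`simulate_night` output."""
    if config.n_nights < 1:
        raise ConfigError("n_nights: must be >= 1 to simulate a cohort")
    return [
        simulate_night(replace(config, ne_fraction=1.0 if i % 2 == 0 else 0.0), i)
        for i in range(config.n_nights)
    ]


def simulate_uds_session(
    config: SimConfig,
    capacity: float = 200.0,
    duration: float = 600.0,
    session_index: int = 0,
) -> UDSRecord:
    """Simulate an in-hospital saline-filling session.

    The bladder is filled at a constant rate from empty to ``capacity`` cc
    over ``duration`` seconds; pelvic bioimpedance decreases linearly with
    injected volume (``uds_slope_per_cc`` ohm/cc) plus the configured noise
    and movement artifacts.
    """
    if capacity <= 0:
        raise ConfigError("capacity: must be > 0")
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(1_000_000 + session_index,))
    )
    volume_rate = 1.0  # Hz
    n_vol = int(round(duration * volume_rate)) + 1
    volume = np.linspace(0.0, capacity, n_vol)

    n_bi = int(round(duration * config.bi_rate))
    t_bi = np.arange(n_bi) / config.bi_rate
    baseline = rng.uniform(*config.bi_baseline_range)
    vol_at_bi = np.interp(t_bi, np.arange(n_vol) / volume_rate, volume)
    bi = baseline + config.uds_slope_per_cc * vol_at_bi
    bi = bi + _smooth_noise(
        rng, n_bi, config.bi_rate, config.bi_noise_sd, config.bi_noise_knot_seconds
    )
    for ts in _poisson_event_times(rng, config.artifact_rate, duration):
        dur = rng.uniform(*config.artifact_duration)
        a = int(ts * config.bi_rate)
        b = min(n_bi, a + max(1, int(dur * config.bi_rate)))
        bi[a:b] += rng.choice([-1.0, 1.0]) * rng.uniform(1.0, 2.0) * config.artifact_magnitude
    return UDSRecord(
        bi_stream=bi,
        bi_rate=config.bi_rate,
        injected_volume=volume,
        volume_rate=volume_rate,
        capacity=capacity,
    )


def synthetic_ecg(
    beat_times: np.ndarray,
    span: float,
    rate: float,
    rng: np.random.Generator | None = None,
    qrs_amplitude: float = 1.0,
    noise_sd: float = 0.03,
) -> np.ndarray:
    """A minimal ECG waveform: a narrow Gaussian QRS at each beat time.

    Only used in raw-ECG mode to exercise R-peak detection; beat times are
    otherwise emitted directly.
    """
    n = int(round(span * rate))
    t = np.arange(n) / rate
    ecg = np.zeros(n)
    width = 0.012  # s, QRS half-width
    for b in np.asarray(beat_times):
        a = max(0, int((b - 5 * width) * rate))
        z = min(n, int((b + 5 * width) * rate) + 1)
        ecg[a:z] += qrs_amplitude * np.exp(-0.5 * ((t[a:z] - b) / width) ** 2)
    if rng is not None and noise_sd > 0:
        ecg = ecg + rng.normal(0.0, noise_sd, size=n)
    return ecg
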