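"""Limb-movement detection, PLMS series rule, disorder flag, angle trend."""

import numpy as np
import pytest

import nocturne as nc
from nocturne import motion
from nocturne.motion import LMEvent, MotionParams


def make_event(onset, side="left", duration=2.0):
    return LMEvent(side=side, onset=onset, duration=duration, magnitude=0.5)


class TestMagnitude:
    def test_all_zero_signal(self):
        assert motion.movement_magnitude(np.zeros((3000, 3))) == 0.0

    def test_stationary_gravity_near_zero(self):
        accel = np.zeros((3000, 3))
        accel[:, 2] = 1.0  # constant gravity
        assert motion.movement_magnitude(accel) < 1e-6

    def test_burst_amplitude_proportionality(self):
        rng = np.random.default_rng(9)
        t = np.arange(3000) / 100.0

        def burst(a):
            accel = np.zeros((3000, 3))
            accel[:, 0] = a * np.sin(2 * np.pi * 4 * t)
            return motion.movement_magnitude(accel)

        assert burst(0.8) == pytest.approx(2 * burst(0.4), rel=0.02)


class TestDetection:
    def quiet(self, n=60 * 100, seed=10):
        rng = np.random.default_rng(seed)
        accel = rng.normal(0, 0.01, size=(n, 3))
        accel[:, 2] += 1.0
        return accel

    def test_quiet_night_zero_events(self):
        assert motion.detect_limb_movements(self.quiet(), None, "left") == []

    def test_planted_bursts_recovered(self):
        accel = self.quiet(120 * 100)
        t = np.arange(accel.shape[0]) / 100.0
        for onset in (20.0, 60.0, 100.0):
            sel = (t >= onset) & (t < onset + 2.0)
            accel[sel, 0] += 0.4 * np.sin(2 * np.pi * 4 * (t[sel] - onset))
        events = motion.detect_limb_movements(accel, None, "left")
        assert len(events) == 3
        for e, onset in zip(events, (20.0, 60.0, 100.0)):
            assert abs(e.onset - onset) < 0.2

    def test_long_movement_excluded_by_duration_gate(self):
        accel = self.quiet(60 * 100)
        t = np.arange(accel.shape[0]) / 100.0
        sel = (t >= 10.0) & (t < 25.0)  # 15-s continuous movement
        accel[sel, 0] += 0.4 * np.sin(2 * np.pi * 4 * t[sel])
        assert motion.detect_limb_movements(accel, None, "left") == []


class TestSeriesRule:
    def test_qualifying_series_counted(self):
        events = [make_event(100 + 20 * k) for k in range(4)]
        assert motion.plms_index(events, sleep_hours=8.0) == pytest.approx(0.5)

    def test_forty_events_in_8h_is_boundary_index(self):
        events = [make_event(100 + 30 * k) for k in range(40)]
        idx = motion.plms_index(events, sleep_hours=8.0)
        assert idx == pytest.approx(5.0)
        assert motion.has_plms_disorder(idx)

    def test_three_in_a_row_do_not_qualify(self):
        events = [make_event(100 + 20 * k) for k in range(3)]
        assert motion.plms_index(events, sleep_hours=8.0) == 0.0

    def test_wide_spacing_does_not_qualify(self):
        events = [make_event(100 + 120 * k) for k in range(10)]
        assert motion.plms_index(events, sleep_hours=8.0) == 0.0

    def test_mixed_series_brute_force(self):
        # brute-force scan over a constructed event list: one 5-event series
        # with valid gaps, plus isolated events that never qualify
        series = [make_event(200 + g) for g in (0, 10, 50, 140, 160)]
        # gaps 10, 40, 90, 20 -> all within [5, 90]: one run of 5
        isolated = [make_event(1000), make_event(3000), make_event(5000)]
        idx = motion.plms_index(series + isolated, sleep_hours=2.0)
        assert idx == pytest.approx(5 / 2.0)

    def test_permuting_isolated_events_never_changes_index(self):
        series = [make_event(100 + 20 * k) for k in range(6)]
        base = motion.plms_index(series + [make_event(2000), make_event(4000)], 8.0)
        moved = motion.plms_index(series + [make_event(4500), make_event(6000)], 8.0)
        assert base == moved

    def test_invalid_sleep_hours(self):
        with pytest.raises(ValueError):
            motion.plms_index([], sleep_hours=0.0)


class TestDisorderFlag:
    @pytest.mark.parametrize("index, expected", [(4.99, False), (5.0, True), (15.59, True)])
    def test_threshold(self, index, expected):
        assert motion.has_plms_disorder(index) is expected

    def test_monotone_in_index(self):
        flags = [motion.has_plms_disorder(x) for x in np.linspace(0, 20, 50)]
        assert flags == sorted(flags)


class TestAngleTrend:
    def test_zero_angular_velocity(self):
        assert motion.angle_difference_trend(np.zeros((3000, 3))) == 0.0

    def test_constant_rotation_proportional(self):
        gyro = np.zeros((3000, 3))
        gyro[:, 1] = 10.0  # deg/s
        t1 = motion.angle_difference_trend(gyro)
        gyro[:, 1] = 20.0
        assert motion.angle_difference_trend(gyro) == pytest.approx(2 * t1, rel=1e-6)

    def test_sign_matches_rotation_direction(self):
        gyro = np.zeros((3000, 3))
        gyro[:, 0] = -15.0
        assert motion.angle_difference_trend(gyro) < 0


class TestCohortRecovery:
    def test_plms_index_recovered_within_15_percent(self):
        # pooled over 20 short nights at the default cohort-mean target
        cfg = nc.SimConfig(seed=40, n_nights=20, sleep_duration=1800.0, ne_fraction=0.0)
        total_detected_rate = []
        for i in range(cfg.n_nights):
            night = nc.simulate_night(cfg, i)
            frame = nc.extract_features(night, modalities=("lm",))
            total_detected_rate.append(frame["plms_index"].iloc[0])
        mean_idx = float(np.mean(total_detected_rate))
        assert abs(mean_idx - cfg.plm_index_target) / cfg.plm_index_target <= 0.15
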