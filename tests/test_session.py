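"""Session I/O round-trips, windowing, gap interpolation, wet-moment detection."""

import numpy as np
import pytest

import nocturne as nc
from nocturne.session import (
    ChannelStream,
    SensorNight,
    SessionError,
    detect_wet_moment,
    read_night,
    resample_and_align,
    write_night,
)


def tiny_night(span=120.0, seed=0):
    cfg = nc.SimConfig(seed=seed, sleep_duration=span, ne_fraction=0.0)
    return nc.simulate_night(cfg, 0)


class TestChannelModel:
    def test_declared_rate_enforced(self):
        with pytest.raises(SessionError, match="250"):
            ChannelStream("bi", 100.0, 0.0, np.zeros(100))

    def test_vector_channel_shape_enforced(self):
        with pytest.raises(SessionError, match="accel_l"):
            ChannelStream("accel_l", 100.0, 0.0, np.zeros(100))

    def test_truncated_stream_rejected(self):
        ch = ChannelStream("bi", 250.0, 0.0, np.zeros(250 * 30))
        with pytest.raises(SessionError, match="bi"):
            SensorNight("s", "n", {"bi": ch}, False, None, collection_span=60.0)

    def test_ne_flag_consistency(self):
        ch = ChannelStream("bi", 250.0, 0.0, np.zeros(250 * 30))
        with pytest.raises(SessionError):
            SensorNight("s", "n", {"bi": ch}, True, None, collection_span=30.0)


@pytest.mark.parametrize("fmt", ["csv", "h5"])
class TestRoundTrip:
    def test_round_trip_identity(self, tmp_path, fmt):
        night = tiny_night()
        target = tmp_path / ("night.h5" if fmt == "h5" else "night_dir")
        write_night(night, target)
        back = read_night(target)
        assert back.subject_id == night.subject_id
        assert back.is_ne_day == night.is_ne_day
        assert back.collection_span == night.collection_span
        assert set(back.channels) == set(night.channels)
        for name, ch in night.channels.items():
            np.testing.assert_allclose(back.channels[name].samples, ch.samples, rtol=1e-12)

    def test_ne_metadata_round_trip(self, tmp_path, fmt):
        cfg = nc.SimConfig(seed=3, sleep_duration=120.0, ne_fraction=1.0)
        night = nc.simulate_night(cfg, 0)
        target = tmp_path / ("ne.h5" if fmt == "h5" else "ne_dir")
        write_night(night, target)
        back = read_night(target)
        assert back.is_ne_day
        assert back.ne_moment == pytest.approx(night.ne_moment)


class TestReadErrors:
    def test_missing_bi_channel(self, tmp_path):
        night = tiny_night()
        d = tmp_path / "n"
        write_night(night, d)
        (d / "bi.csv").unlink()
        with pytest.raises(SessionError, match="bi"):
            read_night(d)

    def test_nonexistent_path(self, tmp_path):
        with pytest.raises(SessionError):
            read_night(tmp_path / "nope")


class TestWindowing:
    def test_window_count(self):
        night = tiny_night(span=300.0)
        grid = resample_and_align(night)
        assert grid.n_windows == 10
        assert len(grid.bi) == 10
        assert all(w.size == 30 * 250 for w in grid.bi)

    def test_too_short_night_raises(self):
        ch = ChannelStream("bi", 250.0, 0.0, np.zeros(250 * 10))
        night = SensorNight("s", "n", {"bi": ch}, False, None, collection_span=10.0)
        with pytest.raises(SessionError, match="shorter"):
            resample_and_align(night)

    def test_constant_channel_constant_aggregates(self):
        ch = ChannelStream("bi", 250.0, 0.0, np.full(250 * 60, 42.0))
        night = SensorNight("s", "n", {"bi": ch}, False, None, collection_span=60.0)
        grid = resample_and_align(night)
        for w in grid.bi:
            assert (w == 42.0).all()

    def test_short_gap_linearly_interpolated(self):
        x = np.linspace(0, 59.9, 250 * 60) * 2.0 + 100.0
        x_gapped = x.copy()
        a, b = 250 * 20, 250 * 25  # 5-s dropout
        x_gapped[a:b] = np.nan
        ch = ChannelStream("bi", 250.0, 0.0, x_gapped)
        night = SensorNight("s", "n", {"bi": ch}, False, None, collection_span=60.0)
        grid = resample_and_align(night, gap_limit=10.0)
        filled = np.concatenate(grid.bi)
        # the underlying signal is linear, so interpolation recovers it exactly
        np.testing.assert_allclose(filled[a:b], x[a:b], rtol=1e-9)
        assert not grid.missing.any()

    def test_long_gap_flags_windows_missing(self):
        x = np.full(250 * 90, 100.0)
        x[250 * 35 : 250 * 65] = np.nan  # 30-s dropout > limit, spans two windows
        ch = ChannelStream("bi", 250.0, 0.0, x)
        night = SensorNight("s", "n", {"bi": ch}, False, None, collection_span=90.0)
        grid = resample_and_align(night, gap_limit=10.0)
        assert grid.missing.tolist() == [False, True, True]


class TestWetMoment:
    def make_moisture(self, x):
        return ChannelStream("moisture", 250.0, 0.0, np.asarray(x, dtype=float))

    def test_constant_dry_returns_none(self):
        assert detect_wet_moment(self.make_moisture(np.full(250 * 60, 8000.0))) is None

    def test_step_detected_at_step_time(self):
        x = np.full(250 * 120, 8000.0)
        x[250 * 80 :] = 300.0
        t = detect_wet_moment(self.make_moisture(x))
        assert t == pytest.approx(80.0, abs=1.0)

    def test_step_at_final_sample_detected_there(self):
        x = np.full(250 * 60, 8000.0)
        x[-1] = 100.0
        t = detect_wet_moment(self.make_moisture(x))
        assert t == pytest.approx((x.size - 1) / 250.0, abs=0.01)

    def test_simulated_ne_night_within_30s(self, ne_night):
        t = detect_wet_moment(ne_night.channel("moisture"))
        assert t is not None
        assert abs(t - ne_night.true_ne_moment) <= 30.0

    def test_no_false_positive_on_simulated_dry_night(self, dry_night):
        assert detect_wet_moment(dry_night.channel("moisture")) is None
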