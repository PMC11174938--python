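"""Simulator contracts: determinism, planted ground truth, config validation."""

import numpy as np
import pytest

import nocturne as nc
from nocturne.simulate import ConfigError, simulate_balanced_cohort


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs, field",
        [
            (dict(ne_fraction=1.2), "ne_fraction"),
            (dict(hr_ramp_probability=-0.1), "hr_ramp_probability"),
            (dict(sleep_duration=0.0), "sleep_duration"),
            (dict(bi_rate=-250.0), "bi_rate"),
            (dict(moisture_dry_level=100.0, moisture_wet_level=200.0), "moisture_wet_level"),
            (dict(plm_series_length=(3, 8)), "plm_series_length"),
            (dict(plm_inter_onset=(2.0, 60.0)), "plm_inter_onset"),
            (dict(plm_duration=(0.1, 4.0)), "plm_duration"),
            (dict(ne_window=(0.8, 0.2)), "ne_window"),
        ],
    )
    def test_invalid_config_names_field(self, kwargs, field):
        with pytest.raises(ConfigError, match=field):
            nc.SimConfig(**kwargs)

    def test_empty_cohort_is_an_error(self):
        with pytest.raises(ConfigError, match="n_nights"):
            nc.simulate_cohort(nc.SimConfig(n_nights=0))


class TestDeterminism:
    def test_same_seed_and_index_bit_identical(self, short_config):
        a = nc.simulate_night(short_config, 3)
        b = nc.simulate_night(short_config, 3)
        for name in a.channels:
            np.testing.assert_array_equal(a.channels[name].samples, b.channels[name].samples)
        assert a.ne_moment == b.ne_moment

    def test_different_indices_differ(self, short_config):
        a = nc.simulate_night(short_config, 0)
        b = nc.simulate_night(short_config, 1)
        assert not np.array_equal(a.channel("bi").samples, b.channel("bi").samples)

    def test_cohort_regeneration_identical_assignment(self):
        cfg = nc.SimConfig(seed=5, n_nights=10, sleep_duration=120.0)
        flags1 = [n.is_ne_day for n in nc.simulate_cohort(cfg)]
        flags2 = [n.is_ne_day for n in nc.simulate_cohort(cfg)]
        assert flags1 == flags2


class TestNightStructure:
    def test_channel_lengths_match_rates(self, short_config):
        night = nc.simulate_night(short_config, 0)
        span = night.collection_span
        assert abs(night.channel("bi").samples.size - span * 250) <= 1
        assert abs(night.channel("moisture").samples.size - span * 250) <= 1
        assert abs(night.channel("accel_l").samples.shape[0] - span * 100) <= 1

    def test_ne_fraction_one_forces_wetting(self):
        cfg = nc.SimConfig(seed=1, n_nights=5, ne_fraction=1.0, sleep_duration=600.0)
        for night in nc.simulate_cohort(cfg):
            assert night.is_ne_day and night.true_ne_moment is not None
            assert night.true_ne_moment <= night.collection_span

    def test_moisture_constant_dry_on_dry_nights(self, dry_night):
        moist = dry_night.channel("moisture").samples
        cfg_dry = 10_000.0
        assert abs(moist.mean() - cfg_dry) < 50
        assert moist.min() > 0.9 * cfg_dry

    def test_moisture_drops_at_wetting_moment(self, ne_night):
        moist = ne_night.channel("moisture").samples
        k = int(ne_night.true_ne_moment * 250)
        assert moist[:k - 250].min() > 5000
        assert moist[k + 250:].max() < 2000

    def test_planted_events_inside_night(self, ne_night):
        for e in ne_night.planted_lm_events:
            assert 0 <= e.onset <= ne_night.collection_span
            assert 0.5 <= e.duration <= 10.0

    def test_balanced_cohort_alternates(self):
        cfg = nc.SimConfig(seed=2, n_nights=6, sleep_duration=120.0)
        flags = [n.is_ne_day for n in simulate_balanced_cohort(cfg)]
        assert flags == [True, False, True, False, True, False]


class TestPlantedRates:
    def test_ne_count_within_binomial_3sigma(self):
        cfg = nc.SimConfig(seed=9, n_nights=100, ne_fraction=0.45, sleep_duration=60.0)
        count = sum(n.is_ne_day for n in nc.simulate_cohort(cfg))
        sigma = np.sqrt(100 * 0.45 * 0.55)
        assert abs(count - 45) <= 3 * sigma

    def test_planted_plm_count_within_poisson_3sigma(self):
        # rate 10/h over 8 h -> ~80 in-series events
        cfg = nc.SimConfig(seed=10, sleep_duration=8 * 3600.0, plm_index_target=10.0)
        night = nc.simulate_night(cfg, 0)
        count = sum(e.in_series for e in night.planted_lm_events)
        assert abs(count - 80) <= 3 * np.sqrt(80)

    def test_hr_ramp_only_on_ne_nights(self):
        cfg = nc.SimConfig(seed=12, n_nights=20, ne_fraction=0.5,
                           sleep_duration=120.0, hr_ramp_probability=1.0)
        for night in nc.simulate_cohort(cfg):
            assert night.hr_ramp_present == night.is_ne_day


class TestUDS:
    def test_capacity_validation(self):
        with pytest.raises(ConfigError, match="capacity"):
            nc.simulate_uds_session(nc.SimConfig(), capacity=-5)

    def test_noiseless_session_strictly_decreasing(self):
        cfg = nc.SimConfig(seed=3, bi_noise_sd=0.0, artifact_rate=0.0)
        rec = nc.simulate_uds_session(cfg, capacity=200.0, duration=300.0)
        assert (np.diff(rec.bi_stream) <= 0).all()
        assert (np.diff(rec.bi_stream) < 0).any()

    def test_noiseless_correlation_is_minus_one(self):
        cfg = nc.SimConfig(seed=3, bi_noise_sd=0.0, artifact_rate=0.0)
        rec = nc.simulate_uds_session(cfg, capacity=200.0, duration=300.0)
        t_bi = np.arange(rec.bi_stream.size) / rec.bi_rate
        vol = np.interp(t_bi, np.arange(rec.injected_volume.size) / rec.volume_rate,
                        rec.injected_volume)
        r = np.corrcoef(rec.bi_stream, vol)[0, 1]
        assert r == pytest.approx(-1.0, abs=1e-9)

    def test_volume_monotone_to_capacity(self):
        rec = nc.simulate_uds_session(nc.SimConfig(seed=4), capacity=150.0)
        assert (np.diff(rec.injected_volume) >= 0).all()
        assert rec.injected_volume[-1] == pytest.approx(150.0)
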