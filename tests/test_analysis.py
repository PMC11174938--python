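"""Cohort summaries and correlation analyses."""

import numpy as np
import pandas as pd
import pytest

import nocturne as nc
from nocturne import analysis, bladder


def make_frame(values, is_ne=False, night_id="n0"):
    n = len(values)
    frame = pd.DataFrame(
        {"window": np.arange(n), "time": (np.arange(n) + 1) * 30.0,
         "feat": values, "missing": False}
    )
    frame.attrs.update(is_ne_day=is_ne, night_id=night_id, ne_moment=None)
    return frame


class TestPearson:
    def test_perfect_positive(self):
        x = np.arange(10.0)
        assert analysis.pearson(x, 2 * x)[0] == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.arange(10.0)
        assert analysis.pearson(x, -x)[0] == pytest.approx(-1.0)

    def test_matches_brute_force_formula(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = rng.integers(3, 50)
            x, y = rng.normal(size=n), rng.normal(size=n)
            r, _ = analysis.pearson(x, y)
            brute = ((x - x.mean()) * (y - y.mean())).sum() / (
                np.sqrt(((x - x.mean()) ** 2).sum()) * np.sqrt(((y - y.mean()) ** 2).sum())
            )
            assert r == pytest.approx(brute, abs=1e-12)

    def test_symmetric_and_affine_invariant(self):
        rng = np.random.default_rng(12)
        x, y = rng.normal(size=20), rng.normal(size=20)
        r_xy = analysis.pearson(x, y)[0]
        assert analysis.pearson(y, x)[0] == pytest.approx(r_xy)
        assert analysis.pearson(3 * x + 5, y)[0] == pytest.approx(r_xy)
        assert analysis.pearson(-2 * x, y)[0] == pytest.approx(-r_xy)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            analysis.pearson(np.ones(5), np.arange(5.0))


class TestEventDriven:
    def test_constant_feature_identical_anchors(self):
        frames = [make_frame([5.0] * 60, night_id=f"n{i}") for i in range(4)]
        out = analysis.event_driven_summary(frames, "feat", k_windows=5)
        meds = {a: out[("dry", a)].median for a in ("start", "middle", "end")}
        assert meds["start"] == meds["middle"] == meds["end"] == 5.0

    def test_decreasing_feature_orders_anchors(self):
        frames = [make_frame(np.linspace(10, 0, 90), night_id=f"n{i}") for i in range(3)]
        out = analysis.event_driven_summary(frames, "feat", k_windows=5)
        assert out[("dry", "end")].median < out[("dry", "middle")].median < out[("dry", "start")].median

    def test_short_nights_excluded(self):
        frames = [make_frame([1.0] * 10), make_frame([2.0] * 60, night_id="long")]
        out = analysis.event_driven_summary(frames, "feat", k_windows=5)
        assert out[("dry", "start")].per_night.size == 1

    def test_simulated_bid_falls_start_to_end(self, ne_frame, dry_frame):
        out = analysis.event_driven_summary([ne_frame, dry_frame], "BID", k_windows=10)
        for stratum in ("ne", "dry"):
            assert out[(stratum, "end")].median < out[(stratum, "start")].median


class TestSequential:
    def test_constant_profile_flat(self):
        out = analysis.sequential_summary([make_frame([3.0] * 50)], "feat", n_bins=5)
        assert np.allclose(out["dry"].bin_median, 3.0)

    def test_linear_profile_hits_bin_centers(self):
        n = 1000
        values = np.linspace(0, 1, n)
        out = analysis.sequential_summary([make_frame(values)], "feat", n_bins=10)
        centers = (out["dry"].bin_edges[:-1] + out["dry"].bin_edges[1:]) / 2
        assert np.allclose(out["dry"].bin_mean, centers, atol=0.01)

    def test_steeper_ne_slope_visible(self):
        dry = [make_frame(np.linspace(0, -10, 60), night_id=f"d{i}") for i in range(3)]
        ne = [make_frame(np.linspace(0, -30, 60), is_ne=True, night_id=f"n{i}") for i in range(3)]
        out = analysis.sequential_summary(dry + ne, "feat", n_bins=5)
        slope_dry = out["dry"].bin_mean[-1] - out["dry"].bin_mean[0]
        slope_ne = out["ne"].bin_mean[-1] - out["ne"].bin_mean[0]
        assert slope_ne < slope_dry < 0


@pytest.fixture(scope="module")
def sessions():
    cfg = nc.SimConfig(seed=13)
    return [nc.simulate_uds_session(cfg, capacity=150 + 10 * i, session_index=i)
            for i in range(10)]


class TestUDSCorrelations:
    def test_noiseless_bid_correlation_is_perfect(self):
        cfg = nc.SimConfig(seed=14, bi_noise_sd=0.0, artifact_rate=0.0)
        sessions = [nc.simulate_uds_session(cfg, capacity=200.0, session_index=i)
                    for i in range(3)]
        table = analysis.uds_feature_correlations(sessions)
        row = table[(table.feature == "BID") & (table.scope == "per_session_mean")]
        assert row["r_abs"].iloc[0] == pytest.approx(1.0, abs=1e-6)

    def test_bid_beats_raw_bi_with_artifacts(self, sessions):
        table = analysis.uds_feature_correlations(sessions)
        per = table[table.scope == "per_session_mean"].set_index("feature")
        assert per.loc["BID", "r_abs"] > per.loc["BI_raw", "r_abs"]

    def test_bid_correlation_is_negative(self, sessions):
        table = analysis.uds_feature_correlations(sessions)
        per = table[table.scope == "per_session_mean"].set_index("feature")
        assert per.loc["BID", "r_signed"] < 0

    def test_shuffled_volume_kills_correlation(self, sessions):
        rng = np.random.default_rng(15)
        shuffled = []
        for s in sessions:
            v = s.injected_volume.copy()
            rng.shuffle(v)
            shuffled.append(
                nc.simulate.UDSRecord(s.bi_stream, s.bi_rate, v, s.volume_rate, s.capacity)
            )
        table = analysis.uds_feature_correlations(shuffled)
        row = table[(table.feature == "BID") & (table.scope == "pooled")]
        assert abs(row["r_signed"].iloc[0]) < 0.4

    def test_too_few_sessions_rejected(self, sessions):
        with pytest.raises(ValueError):
            analysis.uds_feature_correlations(sessions[:2])
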