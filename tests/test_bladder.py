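"""Bladder-feature oracles: worked examples, brute-force accumulation, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nocturne import bladder


def brute_bid(bi, d_upper, T):
    """Independent accumulation of clipped successive differences."""
    total = 0.0
    for i in range(1, T + 1):
        d = bi[i] - bi[i - 1]
        if abs(d) <= d_upper:
            total += d
    return total


def brute_bid_decrease(bi, d_upper, T):
    """Independent accumulation of bounded decreases."""
    total = 0.0
    for i in range(1, T + 1):
        if 0 <= bi[i - 1] - bi[i] <= d_upper:
            total += bi[i] - bi[i - 1]
    return total


class TestDeltaSeries:
    def test_worked_example_with_clipping(self):
        d = bladder.bi_delta_series([100, 99, 97, 120], d_upper=5)
        assert d.tolist() == [-1, -2, 0]  # the +23 jump is clipped

    def test_constant_series_all_zero(self):
        assert bladder.bi_delta_series([7.0] * 10, d_upper=1).tolist() == [0.0] * 9

    def test_infinite_bound_telescopes(self):
        rng = np.random.default_rng(0)
        bi = rng.normal(size=50)
        assert np.isclose(bladder.bi_delta_series(bi, np.inf).sum(), bi[-1] - bi[0])

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            bladder.bi_delta_series([1.0], d_upper=1)


class TestBid:
    @pytest.mark.parametrize(
        "bi, d_upper, T, expected",
        [
            ([100, 99, 97, 120], 5, 3, -3),
            ([100, 102, 101], 5, 2, 1),
        ],
    )
    def test_worked_examples(self, bi, d_upper, T, expected):
        assert bladder.bid(bi, d_upper, T) == pytest.approx(expected)

    def test_matches_brute_force_on_random_series(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = rng.integers(5, 40)
            bi = rng.normal(100, 5, size=n)
            d_upper = rng.uniform(0.5, 10)
            T = int(rng.integers(1, n))
            assert bladder.bid(bi, d_upper, T) == pytest.approx(
                brute_bid(bi, d_upper, T), abs=1e-12
            )

    def test_telescoping_when_no_diff_exceeds_bound(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            bi = np.cumsum(rng.uniform(-0.9, 0.9, size=30)) + 100
            for T in (1, 10, 29):
                assert bladder.bid(bi, 1.0, T) == pytest.approx(bi[T] - bi[0], abs=1e-12)

    def test_inserted_artifact_spike_changes_nothing(self):
        # splice a 5-sample spike between two equal samples: both edge steps
        # exceed the bound and are clipped, so the accumulated value is unchanged
        bi = np.repeat(np.linspace(100, 90, 25), 2)  # duplicated samples
        # insert between indices 18 and 19, which hold the same value
        spiked = np.concatenate([bi[:19], np.full(5, bi[18] + 30.0), bi[19:]])
        base = bladder.bid(bi, 5.0, len(bi) - 1)
        assert bladder.bid(spiked, 5.0, len(spiked) - 1) == pytest.approx(base)

    def test_out_of_range_T(self):
        with pytest.raises(ValueError):
            bladder.bid([1, 2, 3], 5, T=3)


class TestBidDecrease:
    @pytest.mark.parametrize(
        "bi, d_upper, T, expected",
        [
            ([100, 102, 101], 5, 2, -1),  # the rise contributes 0
            ([100, 99, 97, 120], 5, 3, -3),
        ],
    )
    def test_worked_examples(self, bi, d_upper, T, expected):
        assert bladder.bid_decrease(bi, d_upper, T) == pytest.approx(expected)

    def test_matches_brute_force_and_is_nonincreasing(self):
        rng = np.random.default_rng(43)
        for _ in range(100):
            n = rng.integers(5, 40)
            bi = rng.normal(100, 5, size=n)
            d_upper = rng.uniform(0.5, 10)
            profile = bladder.bid_decrease_profile(bi, d_upper)
            for T in range(1, n):
                assert profile[T - 1] == pytest.approx(
                    brute_bid_decrease(bi, d_upper, T), abs=1e-12
                )
            assert (profile <= 1e-12).all()
            assert (np.diff(profile) <= 1e-12).all()

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(
        st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=30),
        st.floats(0.1, 100.0),
    )
    def test_never_positive_never_increasing(self, bi, d_upper):
        profile = bladder.bid_decrease_profile(np.asarray(bi), d_upper)
        assert (profile <= 1e-9).all()
        assert (np.diff(profile) <= 1e-9).all()


class TestDbid:
    def test_linear_bid_gives_constant_slope(self):
        s = bladder.dbid(np.arange(10) * 2.5, lag=1)
        assert np.allclose(s[1:], 2.5)
        assert np.isnan(s[0])

    def test_constant_bid_gives_zero(self):
        assert np.allclose(bladder.dbid(np.full(8, 3.0), lag=1)[1:], 0.0)

    def test_lag2_is_sum_of_two_lag1_steps(self):
        rng = np.random.default_rng(2)
        s = rng.normal(size=20)
        lag1 = bladder.dbid(s, 1)
        lag2 = bladder.dbid(s, 2)
        assert np.allclose(lag2[2:], lag1[2:] + lag1[1:-1])


class TestClutter:
    def test_constant_window(self):
        assert bladder.clutter([4.2] * 5) == 4.2

    def test_median_robust_to_spike(self):
        assert bladder.clutter([1, 2, 100]) == 2

    def test_spike_insensitive_on_noisy_window(self):
        rng = np.random.default_rng(3)
        w = rng.normal(100, 0.5, size=500)
        spiked = w.copy()
        spiked[100:110] += 50.0
        assert bladder.clutter(spiked) == pytest.approx(bladder.clutter(w), abs=0.05)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            bladder.clutter([])


class TestWindowFeatures:
    def test_windowed_bid_matches_pointwise_bid(self):
        rng = np.random.default_rng(4)
        bi = np.cumsum(rng.uniform(-0.4, 0.35, size=600)) + 200
        windows = [bi[i * 100:(i + 1) * 100] for i in range(6)]
        out = bladder.window_bi_features(windows, rate=10.0, params=bladder.BVParams(d_upper=1.0))
        for w in range(6):
            T = (w + 1) * 100 - 1
            assert out["BID"][w] == pytest.approx(bladder.bid(bi, 1.0, T))
            assert out["BID_decrease"][w] == pytest.approx(bladder.bid_decrease(bi, 1.0, T))

    def test_d_upper_estimate_scales_with_noise(self):
        rng = np.random.default_rng(5)
        small = bladder.estimate_d_upper(rng.normal(0, 0.1, 3000), rate=10.0)
        large = bladder.estimate_d_upper(rng.normal(0, 1.0, 3000), rate=10.0)
        assert large > 5 * small
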