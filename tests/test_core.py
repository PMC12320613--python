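"""Kernel-level checks: local means with adaptive edges and the suppression rule."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from lmsf.core import (
    lmsf_1d,
    lmsf_2d,
    local_mean_1d,
    local_mean_2d,
    n_max,
    oracle_lmsf_2d,
    oracle_local_mean_2d,
    sine_squared_local_mean,
)
from lmsf.synthetic import make_sine_squared_signal


def brute_local_mean_1d(s, n):
    s = np.asarray(s, dtype=float)
    return np.array(
        [s[max(k - n, 0):k + n + 1].mean() for k in range(s.size)]
    )


class TestNMax:
    @pytest.mark.parametrize(
        "rows, cols, expected", [(1000, 1000, 499), (200, 200, 99), (4, 10, 1), (7, 9, 2)]
    )
    def test_bound(self, rows, cols, expected):
        assert n_max(rows, cols) == expected

    @pytest.mark.parametrize("rows, cols", [(3, 100), (100, 3), (1, 1)])
    def test_too_small_rejected(self, rows, cols):
        with pytest.raises(ValueError, match="too small"):
            n_max(rows, cols)


class TestLocalMean1d:
    def test_constant_signal_is_fixed_point(self):
        for n in (1, 2, 10):
            np.testing.assert_array_equal(local_mean_1d([3.5] * 25, n), [3.5] * 25)

    def test_spike_with_adaptive_edges(self):
        # hand-evaluated adaptive windows: divisors 3, 4, 5, 4, 3
        expected = [10 / 3, 10 / 4, 10 / 5, 10 / 4, 10 / 3]
        np.testing.assert_allclose(local_mean_1d([0, 0, 10, 0, 0], 2), expected)

    @given(
        s=hnp.arrays(np.float64, st.integers(2, 40),
                     elements=st.floats(-100, 100, width=32)),
        data=st.data(),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_windowed_average_everywhere(self, s, data):
        n = data.draw(st.integers(1, s.size - 1))
        np.testing.assert_allclose(
            local_mean_1d(s, n), brute_local_mean_1d(s, n), rtol=0, atol=1e-9
        )

    def test_invalid_window_rejected(self):
        for n in (0, 5, 9):
            with pytest.raises(ValueError):
                local_mean_1d([1.0] * 5, n)
        with pytest.raises(ValueError):
            local_mean_1d([1.0, np.nan, 1.0], 1)


class TestLmsf1d:
    def test_constant_positive_signal_kept_at_theta_one(self):
        s = np.full(30, 7.0)
        np.testing.assert_array_equal(lmsf_1d(s, 4, 1.0), s)

    def test_isolated_spike_survives_zeros_are_background(self):
        s = [0, 0, 10, 0, 0]
        np.testing.assert_array_equal(lmsf_1d(s, 2, 0.5), s)

    def test_sine_squared_cutoff_quarter_at_theta_half(self):
        # 75-sample windows = 3 signal periods -> interior local mean exactly 1/2,
        # so theta=0.5 suppresses exactly the samples below 1/4.
        s = make_sine_squared_signal(9, 25)
        n = 37
        mean = local_mean_1d(s, n)
        interior = slice(n, s.size - n)
        np.testing.assert_allclose(mean[interior], 0.5, atol=1e-12)
        out = lmsf_1d(s, n, 0.5)
        np.testing.assert_array_equal(out[interior] == 0, s[interior] < 0.25)

    def test_output_is_zero_or_original(self, rng):
        s = rng.normal(size=200)
        out = lmsf_1d(s, 7, 0.8)
        assert out.shape == s.shape
        assert np.all((out == 0) | (out == s))


class TestLocalMean2d:
    def test_constant_image_constant_to_the_corners(self):
        img = np.full((9, 13), 4.2)
        for n in (1, 3, 8):
            np.testing.assert_allclose(local_mean_2d(img, n), img, rtol=1e-12)

    def test_center_spike_adaptive_windows(self):
        img = np.zeros((3, 3))
        img[1, 1] = 9.0
        expected = np.array([[2.25, 1.5, 2.25], [1.5, 1.0, 1.5], [2.25, 1.5, 2.25]])
        np.testing.assert_allclose(local_mean_2d(img, 1), expected)

    def test_matches_brute_force_oracle(self, rng):
        img = rng.random((20, 20)) * 50
        got = local_mean_2d(img, 3)
        want = oracle_local_mean_2d(img, 3)
        np.testing.assert_allclose(got, want, rtol=1e-9)

    def test_interior_equals_plain_box_mean(self, rng):
        from scipy.ndimage import uniform_filter

        img = rng.random((30, 40)) * 100
        n = 4
        box = uniform_filter(img, size=2 * n + 1, mode="constant")
        got = local_mean_2d(img, n)
        np.testing.assert_allclose(got[n:-n, n:-n], box[n:-n, n:-n], rtol=1e-9)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="valid range"):
            local_mean_2d(np.ones((10, 10)), 0)
        with pytest.raises(ValueError, match="valid range"):
            local_mean_2d(np.ones((10, 10)), 10)
        with pytest.raises(ValueError, match="negative"):
            local_mean_2d(-np.ones((10, 10)), 2)


class TestLmsf2d:
    def test_constant_image_limits(self):
        img = np.full((12, 12), 5.0)
        np.testing.assert_array_equal(lmsf_2d(img, 3, 1.0), img)  # ratio == theta kept
        assert np.all(lmsf_2d(img, 3, 1.0001) == 0)

    def test_center_spike_only_survivor_at_theta_half(self):
        img = np.zeros((3, 3))
        img[1, 1] = 9.0
        out = lmsf_2d(img, 1, 0.5)
        np.testing.assert_array_equal(out, img)
        assert np.count_nonzero(out) == 1

    def test_mask_invariant_under_intensity_scaling(self, rng):
        img = rng.random((25, 25)) * 100
        base = lmsf_2d(img, 4, 0.6) == 0
        for c in (0.01, 3.0, 1e4):
            np.testing.assert_array_equal(lmsf_2d(c * img, 4, 0.6) == 0, base)

    def test_threshold_monotonicity_of_background(self, rng):
        img = rng.random((30, 30)) * 10
        prev = np.zeros((30, 30), dtype=bool)
        for theta in (0.3, 0.5, 0.8, 1.0, 1.2):
            bg = lmsf_2d(img, 5, theta) == 0
            assert np.all(prev <= bg)  # background only grows with theta
            prev = bg

    def test_shape_value_and_dtype_preservation(self, rng):
        img = (rng.random((17, 23)) * 1000).astype(np.uint16)
        out = lmsf_2d(img, 2, 0.5)
        assert out.shape == img.shape and out.dtype == img.dtype
        assert np.all((out == 0) | (out == img))


class TestOracleEquivalence:
    def test_fast_filter_matches_window_enumeration(self, rng):
        """Integral-image filter equals the direct per-pixel window oracle."""
        for _ in range(60):
            K = int(rng.integers(5, 41))
            M = int(rng.integers(5, 41))
            img = rng.random((K, M)) * rng.choice([1.0, 255.0, 65535.0])
            n = int(rng.integers(1, n_max(K, M) + 1))
            theta = float(rng.choice([0.3, 0.5, 1.0]))
            np.testing.assert_allclose(
                local_mean_2d(img, n), oracle_local_mean_2d(img, n), rtol=1e-9
            )
            fast = lmsf_2d(img, n, theta)
            slow = oracle_lmsf_2d(img, n, theta)
            np.testing.assert_array_equal(fast == 0, slow == 0)

    def test_degenerate_single_row_rejected(self):
        with pytest.raises(ValueError):
            oracle_lmsf_2d(np.ones((1, 10)), 1, 0.5)


class TestSineSquaredLocalMean:
    def test_window_of_whole_periods_gives_exactly_half(self):
        for k in (1, 2, 5):
            T = k * np.pi / 2
            t = np.linspace(-3, 3, 17)
            np.testing.assert_allclose(sine_squared_local_mean(t, T), 0.5, atol=1e-15)

    def test_quarter_pi_phase_gives_half_for_any_window(self):
        for T in (0.1, 0.3, 2.0):
            assert sine_squared_local_mean(np.pi / 4, T) == pytest.approx(0.5)

    def test_matches_numerical_quadrature(self):
        from scipy.integrate import quad

        T = 0.3
        for t in (0.0, 0.7, 2.1):
            val, _ = quad(lambda tau: np.sin(t + tau) ** 2, -T, T)
            assert sine_squared_local_mean(t, T) == pytest.approx(
                val / (2 * T), abs=1e-9
            )

    def test_nonpositive_window_rejected(self):
        with pytest.raises(ValueError):
            sine_squared_local_mean(0.0, 0.0)
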