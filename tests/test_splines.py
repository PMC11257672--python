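"""Design-matrix building blocks: running sums, natural splines, cross-basis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from raincross.splines import (
    CrossBasisSpec,
    SplineSpec,
    cross_basis,
    log_lag_knots,
    month_indicators,
    ns_basis,
    percentile_knots,
    running_sum,
)


class TestRunningSum:
    def test_constant_series(self):
        out = running_sum(np.full(60, 2.0), 28)
        assert np.isnan(out[:28]).all()
        assert np.allclose(out[28:], 56.0)

    def test_prior_window_excludes_current_day(self):
        # day index 2 sums days 0..1
        out = running_sum(np.array([5.0, 1.0, 3.0]), 2)
        assert out[2] == 6.0

    def test_window_one_is_lagged_series(self):
        x = np.arange(10.0)
        out = running_sum(x, 1)
        assert np.allclose(out[1:], x[:-1])

    def test_rejects_bad_window(self):
        with pytest.raises(ValueError):
            running_sum(np.ones(5), 5)
        with pytest.raises(ValueError):
            running_sum(np.ones(5), 0)

    def test_rejects_missing_values(self):
        with pytest.raises(ValueError):
            running_sum(np.array([1.0, np.nan, 2.0]), 1)

    @given(st.integers(1, 6), st.integers(1, 6), st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_additivity_over_disjoint_windows(self, w1, w2, seed):
        x = np.random.default_rng(seed).gamma(1.0, 5.0, 40)
        both = running_sum(x, w1 + w2)
        recent = running_sum(x, w1)
        older = np.full_like(x, np.nan)
        older[w1 + w2:] = [x[t - w1 - w2 : t - w1].sum() for t in range(w1 + w2, len(x))]
        t = np.arange(w1 + w2, len(x))
        assert np.allclose(both[t], recent[t] + older[t])


class TestPercentileKnots:
    def test_uniform_grid(self):
        spec = percentile_knots(np.linspace(0, 100, 101), [50, 90])
        assert spec.internal_knots == (50.0, 90.0)
        assert spec.boundary_knots == (0.0, 100.0)

    def test_linear_interpolation_definition(self):
        # brute-force percentile of 1..100: p33 -> 33.67, p67 -> 67.33
        spec = percentile_knots(np.arange(1.0, 101.0), [33, 67])
        assert spec.internal_knots == pytest.approx((33.67, 67.33))

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            percentile_knots(np.full(50, 7.0), [50, 90])

    def test_ignores_nan(self):
        x = np.concatenate([np.linspace(0, 100, 101), [np.nan] * 10])
        spec = percentile_knots(x, [50])
        assert spec.internal_knots == (50.0,)


class TestLogLagKnots:
    def test_max_lag_28(self):
        expected = [28**0.25, 28**0.5, 28**0.75]  # ~[2.3003, 5.2915, 12.1722]
        assert log_lag_knots(28, 3) == pytest.approx(expected, abs=1e-12)

    def test_exact_powers_of_e(self):
        e4 = float(np.exp(4))
        assert log_lag_knots(e4, 3) == pytest.approx([np.e, np.e**2, np.e**3])

    def test_single_knot_is_sqrt(self):
        assert log_lag_knots(28, 1) == pytest.approx([np.sqrt(28)])

    def test_rejects_bad_args(self):
        with pytest.raises(ValueError):
            log_lag_knots(28, 0)
        with pytest.raises(ValueError):
            log_lag_knots(1, 3)


def _tp_natural_design(x, internal, boundary):
    """Truncated-power natural cubic spline basis (independent oracle)."""
    lo, hi = boundary
    allk = [lo, *internal, hi]
    K = len(allk)

    def d(i):
        num = np.clip(x - allk[i], 0, None) ** 3 - np.clip(x - allk[K - 1], 0, None) ** 3
        return num / (allk[K - 1] - allk[i])

    cols = [np.ones_like(x), x] + [d(i) - d(K - 2) for i in range(K - 2)]
    return np.column_stack(cols)


class TestNsBasis:
    @pytest.mark.parametrize("n_internal,intercept", [(0, False), (1, False), (2, False), (2, True), (4, False)])
    def test_dimension_invariant(self, n_internal, intercept):
        knots = tuple(np.linspace(10, 90, n_internal)) if n_internal else ()
        spec = SplineSpec(knots, (0.0, 100.0), intercept=intercept)
        B = ns_basis(np.linspace(0, 100, 50), spec)
        assert B.values.shape[1] == spec.dim == n_internal + 1 + intercept

    def test_no_internal_knots_reduces_to_affine(self):
        spec = SplineSpec((), (0.0, 10.0))
        B = ns_basis(np.linspace(0, 10, 30), spec).values
        assert B.shape[1] == 1
        assert np.abs(np.diff(B[:, 0], 2)).max() < 1e-10

    def test_linear_beyond_boundary(self):
        spec = SplineSpec((30.0, 60.0), (0.0, 100.0))
        g = np.linspace(100, 180, 100)
        B = ns_basis(g, spec).values
        assert np.abs(np.diff(B, 2, axis=0)).max() < 1e-9
        g = np.linspace(-80, 0, 100)
        B = ns_basis(g, spec).values
        assert np.abs(np.diff(B, 2, axis=0)).max() < 1e-9

    def test_matches_truncated_power_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 100, 500)
        spec = percentile_knots(x, [50, 90])
        y = np.sin(x / 20.0) + 0.05 * x
        B = np.column_stack([np.ones_like(x), ns_basis(x, spec).values])
        T = _tp_natural_design(x, spec.internal_knots, spec.boundary_knots)
        fit_b = B @ np.linalg.lstsq(B, y, rcond=None)[0]
        fit_t = T @ np.linalg.lstsq(T, y, rcond=None)[0]
        assert np.abs(fit_b - fit_t).max() < 1e-8

    def test_pointwise_evaluation_invariant_to_duplicates(self):
        spec = SplineSpec((40.0,), (0.0, 100.0))
        x = np.array([10.0, 50.0, 50.0, 90.0])
        B = ns_basis(x, spec).values
        assert np.array_equal(B[1], B[2])

    def test_nan_rows_masked(self):
        spec = SplineSpec((40.0,), (0.0, 100.0))
        B = ns_basis(np.array([np.nan, 50.0]), spec)
        assert not B.usable_mask[0] and B.usable_mask[1]
        assert np.isnan(B.values[0]).all()


class TestCrossBasis:
    def _spec(self, temp, max_lag=28, lag_intercept_only=False):
        var_spec = percentile_knots(temp, [33, 67])
        if lag_intercept_only:
            lag_spec = SplineSpec((), (0.0, float(max_lag)), intercept=True)
            # intercept-only: dim 2 (constant + linear); use constant via 0 knots+intercept
        else:
            lag_spec = SplineSpec(
                tuple(log_lag_knots(max_lag, 3)), (0.0, float(max_lag)), intercept=True
            )
        return CrossBasisSpec(var_spec, lag_spec, max_lag=max_lag)

    def test_column_count_and_mask(self):
        temp = np.random.default_rng(1).normal(20, 5, 120)
        spec = self._spec(temp)
        XB = cross_basis(temp, spec)
        assert XB.values.shape[1] == spec.dim == spec.var_spec.dim * spec.lag_spec.dim
        assert not XB.usable_mask[:28].any() and XB.usable_mask[28:].all()
        assert np.isnan(XB.values[:28]).all()

    def test_constant_temperature_gives_constant_columns(self):
        temp = np.full(60, 21.3)
        var_spec = SplineSpec((20.0,), (15.0, 25.0))
        lag_spec = SplineSpec(tuple(log_lag_knots(28, 3)), (0.0, 28.0), intercept=True)
        XB = cross_basis(temp, CrossBasisSpec(var_spec, lag_spec))
        usable = XB.values[XB.usable_mask]
        assert np.allclose(usable, usable[0])

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(7)
        temp = rng.normal(20, 5, 30)
        var_spec = percentile_knots(temp, [50])
        lag_spec = SplineSpec(tuple(log_lag_knots(28, 3)), (0.0, 28.0), intercept=True)
        spec = CrossBasisSpec(var_spec, lag_spec)
        XB = cross_basis(temp, spec)
        V = ns_basis(temp, var_spec).values
        W = ns_basis(np.arange(29.0), lag_spec).values
        t = 29
        expected = np.array(
            [
                [sum(V[t - l, j] * W[l, k] for l in range(29)) for k in range(W.shape[1])]
                for j in range(V.shape[1])
            ]
        ).ravel()
        assert np.abs(XB.values[t] - expected).max() < 1e-10

    def test_collapses_to_lag_sum_under_flat_lag_basis(self):
        # a lag basis spanning only the constant function makes each cross
        # column proportional to the 29-day running sum of its var column
        rng = np.random.default_rng(3)
        temp = rng.normal(20, 4, 100)
        var_spec = percentile_knots(temp, [50])
        lag_spec = SplineSpec((), (0.0, 28.0), intercept=True)  # dim 2: const+linear span
        V = ns_basis(temp, var_spec).values
        XB = cross_basis(temp, CrossBasisSpec(var_spec, lag_spec))
        # project the cross columns onto {sum_l v_j(t-l), sum_l l*v_j(t-l)}:
        # the constant-lag combination must be reproducible exactly
        t = np.arange(28, 100)
        lag_sums = np.array([[V[ti - np.arange(29), j].sum() for j in range(V.shape[1])] for ti in t])
        W = ns_basis(np.arange(29.0), lag_spec).values
        # solve for the combination of lag-basis cols equal to the constant 1
        c = np.linalg.lstsq(W, np.ones(29), rcond=None)[0]
        assert np.allclose(W @ c, 1.0, atol=1e-10)
        J, K = V.shape[1], W.shape[1]
        combo = XB.values[t].reshape(len(t), J, K) @ c
        assert np.allclose(combo, lag_sums, atol=1e-8)

    def test_series_too_short_rejected(self):
        temp = np.arange(20.0)
        with pytest.raises(ValueError):
            cross_basis(temp, self._spec(np.arange(100.0)))


class TestMonthIndicators:
    def test_january_is_reference(self):
        dates = pd.date_range("2010-01-01", "2010-01-31")
        M = month_indicators(dates).values
        assert M.shape == (31, 11)
        assert (M == 0).all()

    def test_column_sums_equal_month_lengths(self):
        dates = pd.date_range("2010-01-01", "2010-12-31")
        M = month_indicators(dates).values
        expected = [28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31]  # feb..dec 2010
        assert M.sum(axis=0).tolist() == expected

    def test_row_sums_binary(self):
        dates = pd.date_range("2011-06-15", periods=400)
        M = month_indicators(dates).values
        assert set(np.unique(M.sum(axis=1))) <= {0.0, 1.0}
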