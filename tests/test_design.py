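"""Moving averages and natural cubic spline bases."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from casecrossover import (
    DailySeries,
    RankError,
    build_confounder_design,
    natural_cubic_basis,
    trailing_moving_average,
)
from .test_io import _frame


class TestMovingAverage:
    def test_window_one_is_identity(self):
        x = np.array([3.0, 1.0, 4.0, 1.5])
        assert np.array_equal(trailing_moving_average(x, 1), x)

    def test_four_day_window_small_example(self):
        out = trailing_moving_average([1.0, 2.0, 3.0, 4.0], 4)
        assert np.isnan(out[:3]).all()
        assert out[3] == 2.5

    def test_window_below_one_rejected(self):
        with pytest.raises(ValueError):
            trailing_moving_average([1.0], 0)

    def test_missing_value_invalidates_its_windows(self):
        x = np.array([1.0, np.nan, 3.0, 4.0, 5.0])
        out = trailing_moving_average(x, 2)
        assert np.isnan(out[1]) and np.isnan(out[2])
        assert out[3] == 3.5

    def test_exclude_current_uses_strictly_preceding_days(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        out = trailing_moving_average(x, 2, exclude_current=True)
        assert np.isnan(out[:2]).all()
        assert out[2] == 1.5  # mean of days t-2, t-1

    @given(
        st.lists(st.floats(-50, 50), min_size=1, max_size=40),
        st.integers(1, 8),
    )
    def test_agrees_with_loop_and_mean_oracle(self, xs, window):
        x = np.array(xs)
        out = trailing_moving_average(x, window)
        for t in range(len(x)):
            if t < window - 1:
                assert np.isnan(out[t])
            else:
                expected = np.mean(x[t - window + 1 : t + 1])
                assert out[t] == pytest.approx(expected, rel=1e-12, abs=1e-12)


class TestNaturalCubicBasis:
    def test_column_count_equals_df(self):
        x = np.linspace(0, 1, 100)
        for df in (1, 2, 4, 6):
            assert natural_cubic_basis(x, df).values.shape == (100, df)

    def test_zero_second_derivative_beyond_boundary_knots(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 10, 200)
        basis = natural_cubic_basis(x, 5, boundary=(0.0, 10.0))
        # numerically differentiate each basis function outside the boundary
        h = 1e-3
        for grid in (np.linspace(-3, -0.5, 7), np.linspace(10.5, 13, 7)):
            f0 = natural_cubic_basis(np.r_[x, grid], 5, boundary=(0.0, 10.0)).values
            fp = natural_cubic_basis(np.r_[x, grid + h], 5, boundary=(0.0, 10.0)).values
            fm = natural_cubic_basis(np.r_[x, grid - h], 5, boundary=(0.0, 10.0)).values
            second = (fp[200:] - 2 * f0[200:] + fm[200:]) / h**2
            assert np.abs(second).max() < 1e-6

    def test_basis_plus_intercept_reproduces_linear_targets(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(-2, 5, 150)
        y = 3 * x + 1
        B = natural_cubic_basis(x, 6).values
        A = np.column_stack([np.ones_like(x), B])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        assert np.linalg.norm(A @ coef - y) < 1e-8

    def test_too_few_distinct_values_is_rank_error(self):
        with pytest.raises(RankError):
            natural_cubic_basis(np.array([1.0, 1.0, 2.0, 2.0]), 4)

    def test_deterministic_given_inputs(self):
        x = np.random.default_rng(11).normal(size=80)
        b1 = natural_cubic_basis(x, 4)
        b2 = natural_cubic_basis(x, 4)
        assert np.array_equal(b1.values, b2.values)
        assert np.array_equal(b1.knots, b2.knots)

    def test_affine_equivariance_of_fitted_values(self):
        # shifting x shifts the knots and leaves regression fits unchanged
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 10, 120)
        y = np.sin(x) + rng.normal(0, 0.1, 120)
        shift = 37.0

        def fitted(xv):
            B = natural_cubic_basis(xv, 5).values
            A = np.column_stack([np.ones(len(xv)), B])
            coef, *_ = np.linalg.lstsq(A, y, rcond=None)
            return A @ coef

        b0 = natural_cubic_basis(x, 5)
        b1 = natural_cubic_basis(x + shift, 5)
        assert np.allclose(b1.knots - b0.knots, shift, atol=1e-9)
        assert np.allclose(fitted(x), fitted(x + shift), atol=1e-8)

    def test_spans_same_space_as_reference_natural_spline(self):
        # fitted values from an independent natural-spline implementation
        # (patsy's cubic regression basis) must agree: only the spanned
        # function space matters, not the parameterization
        patsy = pytest.importorskip("patsy")
        rng = np.random.default_rng(19)
        x = rng.uniform(0, 10, 300)
        y = np.cos(x) + 0.3 * x + rng.normal(0, 0.2, 300)
        basis = natural_cubic_basis(x, 5)
        ours = basis.values
        theirs = patsy.dmatrix(
            "cr(x, knots=knots, lower_bound=lb, upper_bound=ub) - 1",
            {"x": x, "knots": basis.knots, "lb": basis.boundary[0], "ub": basis.boundary[1]},
            return_type="matrix",
        )

        def fitted(B):
            A = np.column_stack([np.ones(len(x)), B])
            coef, *_ = np.linalg.lstsq(A, y, rcond=None)
            return A @ coef

        assert np.allclose(fitted(ours), fitted(np.asarray(theirs)), atol=1e-8)


class TestConfounderDesign:
    def test_primary_adjustment_has_nine_columns(self):
        s = DailySeries(_frame(n=200))
        d = build_confounder_design(s, 4, 6, 4, 3)
        assert d.matrix.shape[1] == 9
        assert d.spec == (4, 6, 4, 3)

    def test_minimal_design_is_linear_in_inputs(self):
        f = _frame(n=60)
        f["tmean"] = np.linspace(0, 30, 60)
        s = DailySeries(f)
        d = build_confounder_design(s, 1, 1, 1, 1)
        # window 1, df 1: columns are the raw series themselves
        assert np.allclose(d.matrix[:, 0], s.tmean)
        assert np.allclose(d.matrix[:, 1], s.rh)

    def test_valid_mask_leading_false_entries(self):
        s = DailySeries(_frame(n=100))
        d = build_confounder_design(s, 4, 3, 7, 2)
        assert not d.valid_mask[:6].any()
        assert d.valid_mask[6:].all()

    def test_series_shorter_than_window_rejected(self):
        s = DailySeries(_frame(n=3))
        with pytest.raises(ValueError, match="shorter"):
            build_confounder_design(s, 4, 2, 4, 2)
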