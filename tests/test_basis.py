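"""Spline bases: periodicity, cross-basis oracles, prediction contrasts."""

import numpy as np
import pytest

from bathmort.basis import (
    CrossBasisSpec,
    CyclicBasisSpec,
    make_crossbasis,
    make_cyclic_basis,
    natural_cubic_basis,
    predict_from_crossbasis,
)


class TestCyclicBasis:
    def test_df4_gives_four_columns(self):
        bm = make_cyclic_basis(np.arange(1, 366), CyclicBasisSpec(df=4))
        assert bm.values.shape == (365, 4)

    def test_periodic_wrap_continuation(self):
        spec = CyclicBasisSpec(df=4)
        direct = spec.evaluate(np.array([1.0, 2.5, 10.0]))
        wrapped = spec.evaluate(np.array([366.0, 367.5, 375.0]), check=False)
        np.testing.assert_allclose(direct, wrapped, atol=1e-10)

    def test_smooth_across_year_boundary(self):
        # first differences across the 365 -> 1 wrap comparable to interior steps
        spec = CyclicBasisSpec(df=4)
        grid = spec.evaluate(np.arange(1, 366, dtype=float))
        wrap_step = np.abs(grid[0] - grid[-1])
        interior = np.abs(np.diff(grid, axis=0)).max(axis=0)
        assert (wrap_step <= 2 * interior).all()

    def test_cosine_projection_r_squared(self):
        doy = np.arange(1, 366, dtype=float)
        target = np.cos(2 * np.pi * doy / 365)
        B = np.column_stack(
            [np.ones_like(doy), CyclicBasisSpec(df=4).evaluate(doy)]
        )
        fitted = B @ np.linalg.lstsq(B, target, rcond=None)[0]
        ss_res = np.sum((target - fitted) ** 2)
        ss_tot = np.sum((target - target.mean()) ** 2)
        assert 1 - ss_res / ss_tot > 0.99

    def test_full_column_rank(self):
        doy = np.linspace(1, 365, 40)
        assert np.linalg.matrix_rank(CyclicBasisSpec(df=4).evaluate(doy)) == 4

    def test_out_of_range_doy_rejected(self):
        with pytest.raises(ValueError, match="day-of-year"):
            make_cyclic_basis(np.array([0.0, 10.0]))


class TestCrossBasis:
    @pytest.fixture()
    def spec(self):
        return CrossBasisSpec(
            max_lag=21, var_knots=(5.0, 18.0, 24.0), var_boundary=(-5.0, 32.0),
            n_lag_knots=3, reference_temp=16.0,
        )

    def test_column_count_is_product(self, spec):
        assert spec.n_cols == spec.n_var_cols * spec.n_lag_cols

    def test_constant_reference_series_maps_to_zero(self, spec):
        temps = np.full(50, spec.reference_temp)
        bm = make_crossbasis(temps, spec, history=np.full(21, spec.reference_temp))
        # entries cancel pairs of O(1e3) truncated-power terms, so exact zero
        # is only reached to round-off
        np.testing.assert_allclose(bm.values, 0.0, atol=1e-8)

    def test_matches_brute_force_double_loop(self, spec):
        rng = np.random.default_rng(3)
        temps = rng.uniform(-5, 32, 100)
        hist = rng.uniform(-5, 32, 21)
        bm = make_crossbasis(temps, spec, history=hist)
        full = np.r_[hist, temps]
        V = spec.var_basis(full)
        W = spec.lag_basis()
        vref = spec.var_basis(np.array([spec.reference_temp]))[0]
        expected = np.zeros_like(bm.values)
        for t in range(100):
            row = np.zeros((spec.n_var_cols, spec.n_lag_cols))
            for lag in range(22):
                row += np.outer(V[21 + t - lag], W[lag])
            row -= np.outer(vref, W.sum(axis=0))
            expected[t] = row.ravel()
        np.testing.assert_allclose(bm.values, expected, atol=1e-10)

    def test_locality_history_beyond_max_lag_irrelevant(self, spec):
        rng = np.random.default_rng(4)
        temps = rng.uniform(0, 30, 60)
        hist_a = rng.uniform(0, 30, 40)
        hist_b = hist_a.copy()
        hist_b[:19] = rng.uniform(0, 30, 19)  # only entries beyond lag 21 differ
        a = make_crossbasis(temps, spec, history=hist_a)
        b = make_crossbasis(temps, spec, history=hist_b)
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_moving_sum_oracle_linear_var_constant_lag(self):
        # two boundary knots only -> purely linear var basis; single-knot-free
        # lag basis reduced to intercept + linear: use the intercept column
        spec = CrossBasisSpec(
            max_lag=21, var_knots=(), var_boundary=(0.0, 30.0),
            n_lag_knots=0, reference_temp=10.0,
        )
        rng = np.random.default_rng(5)
        temps = rng.uniform(0, 30, 80)
        hist = rng.uniform(0, 30, 21)
        bm = make_crossbasis(temps, spec, history=hist)
        assert spec.n_var_cols == 1
        full = np.r_[hist, temps]
        moving_sum = np.array(
            [sum(full[21 + t - lag] - 10.0 for lag in range(22)) for t in range(80)]
        )
        # intercept lag column (index 0) carries the unweighted moving sum
        np.testing.assert_allclose(bm.values[:, 0], moving_sum, atol=1e-10)

    def test_missing_history_requires_drop_flag(self, spec):
        temps = np.arange(40, dtype=float)
        with pytest.raises(ValueError, match="history"):
            make_crossbasis(temps, spec)
        bm = make_crossbasis(temps, spec, drop_incomplete=True)
        assert (~bm.complete[:21]).all() and bm.complete[21:].all()

    def test_shift_invariance_of_cumulative_curve(self, spec):
        rng = np.random.default_rng(6)
        coef = rng.normal(0, 0.05, spec.n_cols)
        grid = np.linspace(-4, 31, 30)
        shift = 7.3
        spec_shifted = CrossBasisSpec(
            max_lag=21,
            var_knots=tuple(k + shift for k in spec.var_knots),
            var_boundary=(spec.var_boundary[0] + shift, spec.var_boundary[1] + shift),
            n_lag_knots=3,
            reference_temp=spec.reference_temp + shift,
        )
        a = predict_from_crossbasis(coef, np.eye(spec.n_cols), spec, grid)
        b = predict_from_crossbasis(
            coef, np.eye(spec.n_cols), spec_shifted, grid + shift
        )
        np.testing.assert_allclose(a.log_rr, b.log_rr, atol=1e-8)


class TestPrediction:
    @pytest.fixture()
    def spec(self):
        return CrossBasisSpec(
            max_lag=21, var_knots=(8.0, 20.0), var_boundary=(-5.0, 32.0),
            n_lag_knots=2, reference_temp=16.0,
        )

    def test_reference_rr_is_one_any_coef(self, spec):
        rng = np.random.default_rng(7)
        coef = rng.normal(size=spec.n_cols)
        c = predict_from_crossbasis(
            coef, np.eye(spec.n_cols), spec, np.array([spec.reference_temp])
        )
        assert c.rr[0] == pytest.approx(1.0, abs=1e-12)
        assert c.rr_low[0] <= 1.0 <= c.rr_high[0]

    def test_zero_coef_flat_surface(self, spec):
        c = predict_from_crossbasis(
            np.zeros(spec.n_cols), np.zeros((spec.n_cols, spec.n_cols)),
            spec, np.linspace(-5, 32, 20), at="surface",
        )
        np.testing.assert_allclose(c.rr, 1.0, atol=1e-12)

    def test_constant_linear_lag_model_closed_form(self):
        # linear var basis, intercept-only meaningful lag structure: put beta
        # on the (linear var x lag intercept) column -> cumulative log-RR is
        # 22 * beta * (x - ref)
        spec = CrossBasisSpec(
            max_lag=21, var_knots=(), var_boundary=(0.0, 30.0),
            n_lag_knots=0, reference_temp=10.0,
        )
        beta = 0.013
        coef = np.zeros(spec.n_cols)
        coef[0] = beta  # var-linear x lag-intercept
        grid = np.linspace(0, 30, 40)
        c = predict_from_crossbasis(coef, np.zeros((spec.n_cols,) * 2), spec, grid)
        np.testing.assert_allclose(c.log_rr, 22 * beta * (grid - 10.0), atol=1e-8)

    def test_cumulative_equals_sum_of_lag_slices(self, spec):
        rng = np.random.default_rng(8)
        coef = rng.normal(0, 0.1, spec.n_cols)
        grid = np.linspace(-5, 32, 15)
        cum = predict_from_crossbasis(coef, np.eye(spec.n_cols), spec, grid)
        total = sum(
            predict_from_crossbasis(coef, np.eye(spec.n_cols), spec, grid, at=lag).log_rr
            for lag in range(22)
        )
        np.testing.assert_allclose(cum.log_rr, total, atol=1e-8)

    def test_extrapolation_warns(self, spec):
        with pytest.warns(UserWarning, match="extrapolat"):
            predict_from_crossbasis(
                np.zeros(spec.n_cols), np.eye(spec.n_cols), spec, np.array([40.0])
            )


class TestNaturalCubic:
    def test_linear_beyond_boundaries(self):
        knots = np.array([0.0, 5.0, 10.0, 20.0])
        x = np.array([25.0, 30.0, 35.0])
        B = natural_cubic_basis(x, knots)
        # second differences of each column vanish outside the boundary
        second_diff = B[2] - 2 * B[1] + B[0]
        np.testing.assert_allclose(second_diff, 0.0, atol=1e-9)

    def test_column_count(self):
        knots = np.array([0.0, 5.0, 10.0, 20.0])
        x = np.linspace(0, 20, 50)
        assert natural_cubic_basis(x, knots).shape[1] == 3
        assert natural_cubic_basis(x, knots, intercept=True).shape[1] == 4
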