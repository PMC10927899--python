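"""Crank–Nicolson forward model, boundary construction and the inverse fit."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy.special import erfc

from geldiff.diffusion import (
    BoundaryFunction,
    FitGrid,
    boundary_value,
    build_boundary_function,
    classify_boundary_shape,
    fit_diffusion_coefficient,
    fit_eq1,
    select_fit_timepoints,
    solve_crank_nicolson,
)
from geldiff.imaging import GelGeometry, ProfileSeries, baseline_correct
from geldiff.synthetic import SimulationParams, simulate_profiles

DY = 12.50339


def step_boundary(c0):
    return BoundaryFunction(mode="all_spline", knots=[(0.0, c0), (1e9, c0)])


def make_grid(n=229, dy=DY, dt=30.0):
    return FitGrid(y_nodes=dy * np.arange(n), dt=dt)


class TestCrankNicolson:
    def test_zero_boundary_gives_zero_field(self):
        grid = make_grid(51)
        out = solve_crank_nicolson(400.0, step_boundary(0.0), grid, [600.0, 1800.0])
        assert np.all(out.values == 0.0)

    @pytest.mark.parametrize("D", [100.0, 400.0])
    def test_step_boundary_matches_erfc_before_far_wall_is_felt(self, D):
        """Semi-infinite analytic oracle: C0·erfc(y/(2√(Dt)))."""
        grid = make_grid(229)
        c0 = 100.0
        times = [600.0, 1200.0]
        out = solve_crank_nicolson(D, step_boundary(c0), grid, times)
        y = grid.y_nodes
        for t, prof in zip(times, out.values):
            assert 2 * math.sqrt(D * t) < y[-1] / 2  # penetration < half the domain
            exact = c0 * erfc(y / (2.0 * math.sqrt(D * t)))
            assert np.abs(prof - exact).max() < 0.01 * c0

    def test_constant_boundary_steady_state_is_linear(self):
        grid = make_grid(101)
        c0 = 80.0
        t_end = 2.0e6  # ≫ L²/D
        out = solve_crank_nicolson(500.0, step_boundary(c0), grid, [t_end])
        y = grid.y_nodes
        lin = c0 * (1.0 - y / y[-1])
        assert np.abs(out.values[0] - lin).max() < 1e-6 * c0
        mid = (len(y) - 1) // 2
        assert out.values[0][mid] == pytest.approx(c0 / 2.0, abs=1e-6 * c0)

    def test_discrete_maximum_principle_with_smooth_boundary(self):
        """Field stays within the range of boundary history ∪ {0}."""
        grid = make_grid(101)
        bc = BoundaryFunction(mode="exp_then_spline", knots=[(1200.0, 75.0)],
                              i_inf=100.0, beta=math.log(2) / 600.0)
        out = solve_crank_nicolson(400.0, bc, grid, [300.0, 600.0, 1200.0])
        for t, prof in zip(out.times_s, out.values):
            assert prof.min() >= -1e-9
            assert prof.max() <= bc(t) + 1e-9

    def test_grid_refinement_changes_profiles_below_half_percent(self):
        for D in (100.0, 600.0):
            coarse = make_grid(229)
            fine = FitGrid(y_nodes=(DY / 2) * np.arange(457), dt=15.0)
            t = [1800.0]
            bc = step_boundary(50.0)
            u_c = solve_crank_nicolson(D, bc, coarse, t).values[0]
            u_f = solve_crank_nicolson(D, bc, fine, t).values[0][::2]
            assert np.abs(u_c - u_f).max() < 0.005 * 50.0

    def test_rejects_bad_inputs(self):
        grid = make_grid(11)
        with pytest.raises(ValueError):
            solve_crank_nicolson(-1.0, step_boundary(1.0), grid, [60.0])
        with pytest.raises(ValueError):
            FitGrid(y_nodes=DY * np.arange(2))


class TestBoundaryValue:
    def _profiles(self, values):
        values = np.atleast_2d(values)
        return ProfileSeries(y_um=1.0 * np.arange(values.shape[1]), values=values,
                             times_s=60.0 * (1 + np.arange(values.shape[0])))

    def test_constant_profile(self):
        p = self._profiles(np.full((1, 21), 40.0))
        assert boundary_value(p, 10.0, 60.0) == 40.0

    def test_linear_ramp_symmetric_average(self):
        p = self._profiles(np.arange(21, dtype=float))
        assert boundary_value(p, 10.0, 60.0) == pytest.approx(10.0)

    def test_too_close_to_edge(self):
        p = self._profiles(np.arange(21, dtype=float))
        with pytest.raises(ValueError):
            boundary_value(p, 2.0, 60.0)


class TestBoundaryShape:
    def test_concave_growth_selects_exponential(self):
        assert classify_boundary_shape(600, 50, 1200, 75) == "exp_then_spline"

    def test_exact_linearity_tie_breaks_to_spline(self):
        assert classify_boundary_shape(600, 50, 1200, 100) == "all_spline"

    def test_convex_growth_selects_spline(self):
        assert classify_boundary_shape(600, 50, 1200, 120) == "all_spline"

    def test_nonpositive_intensity_warns_and_splines(self):
        with pytest.warns(UserWarning):
            assert classify_boundary_shape(600, -5, 1200, 75) == "all_spline"


class TestFitEq1:
    def test_closed_form_doubled_time(self):
        i_inf, beta = fit_eq1(600, 50, 1200, 75)
        assert i_inf == pytest.approx(100.0, rel=1e-10)
        assert beta == pytest.approx(math.log(2) / 600.0, rel=1e-10)

    def test_general_times_reproduce_inputs(self):
        # points generated from a known saturating curve at non-doubled times
        i_true, b_true = 140.0, 1.7e-3
        t1, t2 = 420.0, 1500.0
        I1 = i_true * (1 - math.exp(-b_true * t1))
        I2 = i_true * (1 - math.exp(-b_true * t2))
        i_inf, beta = fit_eq1(t1, I1, t2, I2)
        assert i_inf * (1 - math.exp(-beta * t1)) == pytest.approx(I1, rel=1e-8)
        assert i_inf * (1 - math.exp(-beta * t2)) == pytest.approx(I2, rel=1e-8)
        assert beta == pytest.approx(b_true, rel=1e-6)

    def test_saturated_inputs_cap_beta(self):
        with pytest.warns(UserWarning):
            i_inf, beta = fit_eq1(600, 50, 1200, 50)
        assert beta == 1.0
        assert i_inf == pytest.approx(50.0, rel=1e-6)


class TestBuildBoundaryFunction:
    def _series_from_boundary(self, times, values, n_y=241):
        # flat transverse profiles whose 11-point average equals the value
        vals = np.tile(np.asarray(values, float)[:, None], (1, n_y))
        return ProfileSeries(y_um=1.0 * np.arange(n_y), values=vals, times_s=np.asarray(times))

    def _geometry(self, n_y=241):
        return GelGeometry(y_donor_interface=0.0, y_acceptor_interface=float(n_y - 1),
                           y_lower_boundary=20.0, y_upper_boundary=float(n_y - 1))

    def test_saturating_samples_recover_the_exponential(self):
        beta = math.log(2) / 600.0
        times = [600.0, 1200.0, 1800.0, 2400.0]
        values = [100 * (1 - math.exp(-beta * t)) for t in times]
        bc = build_boundary_function(self._series_from_boundary(times, values), self._geometry())
        assert bc.mode == "exp_then_spline"
        assert bc(300.0) == pytest.approx(100 * (1 - 2 ** -0.5), rel=1e-6)  # ≈ 29.29
        assert bc(0.0) == 0.0

    def test_linear_boundary_reproduced_exactly(self):
        times = [600.0, 1200.0, 1800.0, 2400.0]
        values = [0.05 * t for t in times]
        bc = build_boundary_function(self._series_from_boundary(times, values), self._geometry())
        assert bc.mode == "all_spline"
        for t in (300.0, 600.0, 900.0, 2400.0):
            assert bc(t) == pytest.approx(0.05 * t, rel=1e-9)
        assert bc(0.0) == 0.0
        assert bc(5000.0) == pytest.approx(values[-1])  # held beyond last knot

    def test_too_few_time_points(self):
        with pytest.raises(ValueError):
            build_boundary_function(
                self._series_from_boundary([600.0], [30.0]), self._geometry()
            )


def _synthetic_baseline_corrected(d_true, n_times=14, noise=0.0, seed=0):
    params = SimulationParams(d_true=d_true, noise_sd=0.0, seed=seed)
    profs = simulate_profiles(params, params.frame_times_s[:n_times])
    if noise:
        rng = np.random.default_rng(seed)
        profs = ProfileSeries(
            y_um=profs.y_um,
            values=profs.values * (1 + noise * rng.standard_normal(profs.values.shape)),
            times_s=profs.times_s,
        )
    geometry = GelGeometry(
        y_donor_interface=0.0,
        y_acceptor_interface=float(profs.y_um[-1]),
        y_lower_boundary=150.0,
        y_upper_boundary=float(profs.y_um[-1]),
    )
    return baseline_correct(profs, "far_segment"), geometry, params


class TestSelectFitTimepoints:
    def test_fast_matrix_selects_earlier_pair_than_slow(self):
        bc_fast, geo, _ = _synthetic_baseline_corrected(500.0)
        bc_slow, _, _ = _synthetic_baseline_corrected(250.0)
        fast = select_fit_timepoints(bc_fast, geo)
        slow = select_fit_timepoints(bc_slow, geo)
        assert fast[0] < slow[0]
        assert fast[1] < slow[1]

    def test_saturated_sink_end_raises_with_diagnosis(self):
        bc, geo, _ = _synthetic_baseline_corrected(300.0)
        # spoil every profile: pretend drug has reached the sink everywhere
        bad = ProfileSeries(y_um=bc.y_um, values=np.abs(bc.values) + 1000.0,
                            times_s=bc.times_s, baseline_mode=bc.baseline_mode)
        with pytest.raises(ValueError, match="sink"):
            select_fit_timepoints(bad, geo)


class TestFitDiffusionCoefficient:
    def test_noiseless_recovery_within_two_percent(self):
        bc, geo, params = _synthetic_baseline_corrected(400.0)
        grid = FitGrid.from_geometry(geo, params.pixel_size_um)
        boundary = build_boundary_function(bc, geo)
        t_a, t_b = select_fit_timepoints(bc, geo)
        keep = np.isin(bc.times_s, [t_a, t_b])
        measured = ProfileSeries(y_um=bc.y_um, values=bc.values[keep],
                                 times_s=bc.times_s[keep], baseline_mode=bc.baseline_mode)
        fit = fit_diffusion_coefficient(measured, boundary, grid)
        assert fit.converged
        assert fit.d_app == pytest.approx(400.0, rel=0.02)
        # accepted LM iterations never increase the SSE
        assert all(b <= a * (1 + 1e-12) for a, b in zip(fit.sse_history, fit.sse_history[1:]))

    def test_intensity_scale_invariance(self):
        """Scaling measurements and boundary ×10 must not move D (linear PDE)."""
        bc, geo, params = _synthetic_baseline_corrected(300.0)
        grid = FitGrid.from_geometry(geo, params.pixel_size_um)
        t_a, t_b = select_fit_timepoints(bc, geo)
        keep = np.isin(bc.times_s, [t_a, t_b])

        def fit_scaled(scale):
            scaled = ProfileSeries(y_um=bc.y_um, values=scale * bc.values,
                                   times_s=bc.times_s, baseline_mode=bc.baseline_mode)
            boundary = build_boundary_function(scaled, geo)
            measured = ProfileSeries(y_um=bc.y_um, values=scale * bc.values[keep],
                                     times_s=bc.times_s[keep], baseline_mode=bc.baseline_mode)
            return fit_diffusion_coefficient(measured, boundary, grid).d_app

        assert fit_scaled(10.0) == pytest.approx(fit_scaled(1.0), rel=1e-6)

    def test_lm_agrees_with_golden_section_search(self):
        """Independent 1-D minimizer on the same SSE lands on the same D."""
        bc, geo, params = _synthetic_baseline_corrected(250.0, noise=0.05, seed=3)
        grid = FitGrid.from_geometry(geo, params.pixel_size_um)
        boundary = build_boundary_function(bc, geo)
        t_a, t_b = select_fit_timepoints(bc, geo)
        keep = np.isin(bc.times_s, [t_a, t_b])
        measured = ProfileSeries(y_um=bc.y_um, values=bc.values[keep],
                                 times_s=bc.times_s[keep], baseline_mode=bc.baseline_mode)
        fit = fit_diffusion_coefficient(measured, boundary, grid)

        idx = np.argmin(np.abs(measured.y_um[None, :] - grid.y_nodes[:, None]), axis=1)
        data = measured.values[:, idx]
        solver_times = [grid.round_time(t) for t in (t_a, t_b)]

        def sse(D):
            pred = solve_crank_nicolson(D, boundary, grid, solver_times)
            return float(((pred.values - data) ** 2).sum())

        res = minimize_scalar(sse, bounds=(50.0, 1000.0), method="bounded",
                              options={"xatol": 1e-4})
        assert fit.d_app == pytest.approx(res.x, rel=1e-3)

    def test_all_zero_measurement_rejected(self):
        grid = make_grid(30)
        measured = ProfileSeries(y_um=grid.y_nodes, values=np.zeros((2, 30)),
                                 times_s=[600.0, 1200.0])
        with pytest.raises(ValueError):
            fit_diffusion_coefficient(measured, step_boundary(1.0), grid)
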