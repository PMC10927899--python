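"""Apparent diffusion coefficient estimation from axial fluorescence profiles.

The forward model is the 1D diffusion equation solved by Crank–Nicolson on a
coarse grid (every 10th pixel, 30 s steps), with a data-driven Dirichlet
condition at the lower (donor-side) fit boundary and a sink (zero) condition
at the gel/acceptor interface. The lower boundary intensity is taken from the
measurements themselves: an exponentially saturating law

    I_LB(t) = I_LB,inf * (1 - exp(-beta * t))

fitted to the first two measured boundary values when the early rise is
concave, continued by a linear spline through the later values; when the
early rise is linear or convex the whole boundary is a linear spline. The
single free parameter D is then found by a Levenberg–Marquardt fit of the
predicted profiles to two measured profiles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from ._pde import crank_nicolson_1d
from .imaging import GelGeometry, ProfileSeries

__all__ = [
    "BoundaryFunction",
    "FitGrid",
    "DiffusionFit",
    "boundary_value",
    "classify_boundary_shape",
    "fit_eq1",
    "build_boundary_function",
    "solve_crank_nicolson",
    "select_fit_timepoints",
    "fit_diffusion_coefficient",
    "estimate_diffusion_coefficient",
]

BoundaryMode = Literal["exp_then_spline", "all_spline"]


@dataclass(frozen=True)
class BoundaryFunction:
    """Lower-boundary intensity vs time since drug addition.

    Evaluates to 0 at t = 0 in both modes; beyond the last knot the last
    value is held.
    """

    mode: BoundaryMode
    knots: np.ndarray  # (k, 2) array of (time s, intensity a.u.)
    i_inf: Optional[float] = None
    beta: Optional[float] = None

    def __post_init__(self):
        knots = np.atleast_2d(np.asarray(self.knots, dtype=float))
        object.__setattr__(self, "knots", knots)
        if self.mode == "exp_then_spline" and (self.i_inf is None or self.beta is None):
            raise ValueError("exp_then_spline mode requires i_inf and beta")

    @property
    def t_exp_end(self) -> float:
        """End of the exponential segment (the second measurement time)."""
        return float(self.knots[0, 0]) if self.mode == "exp_then_spline" else 0.0

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        kt, kv = self.knots[:, 0], self.knots[:, 1]
        spline = np.interp(t, kt, kv, left=np.nan, right=kv[-1])
        if self.mode == "exp_then_spline":
            expo = self.i_inf * -np.expm1(-self.beta * t)
            out = np.where(t <= self.t_exp_end, expo, spline)
        else:
            # anchor at (0, 0)
            out = np.where(t <= kt[0], np.interp(t, np.r_[0.0, kt[0]], np.r_[0.0, kv[0]]), spline)
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class FitGrid:
    """Spatial/temporal discretization of the fitting solver.

    Nodes are every 10th pixel between the lower and upper fit boundaries
    (12.50339 µm at the native pixel size of 1.250339 µm); the time step is
    30 s.
    """

    y_nodes: np.ndarray  # µm, uniform spacing
    dt: float = 30.0

    def __post_init__(self):
        y = np.asarray(self.y_nodes, dtype=float)
        object.__setattr__(self, "y_nodes", y)
        if y.size < 3:
            raise ValueError("fit grid needs at least 3 nodes")
        d = np.diff(y)
        if not np.allclose(d, d[0], rtol=1e-9):
            raise ValueError("fit grid must be uniform")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def dy(self) -> float:
        return float(self.y_nodes[1] - self.y_nodes[0])

    @property
    def n_nodes(self) -> int:
        return self.y_nodes.size

    @classmethod
    def from_geometry(
        cls, geometry: GelGeometry, pixel_size_um: float, subsample: int = 10, dt: float = 30.0
    ) -> "FitGrid":
        """Grid spanning [y_lower_boundary, y_upper_boundary] at every
        ``subsample``-th pixel."""
        dy = subsample * pixel_size_um
        n = int(math.floor((geometry.y_upper_boundary - geometry.y_lower_boundary) / dy)) + 1
        y = geometry.y_lower_boundary + dy * np.arange(n)
        return cls(y_nodes=y, dt=dt)

    def round_time(self, t: float) -> float:
        """Nearest solver step (the alignment error is at most dt/2)."""
        return self.dt * round(t / self.dt)


@dataclass
class DiffusionFit:
    """Result of the inverse fit."""

    d_app: float  # µm²/s
    sse: float
    n_iterations: int
    converged: bool
    times_used: tuple  # (t_a, t_b) s, as measured
    solver_times: tuple  # times rounded to the solver step
    boundary: BoundaryFunction
    grid: FitGrid
    baseline_mode: Optional[str] = None
    d0: Optional[float] = None
    sse_history: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "d_app_um2_per_s": self.d_app,
            "sse": self.sse,
            "n_iterations": self.n_iterations,
            "converged": self.converged,
            "times_used_s": list(self.times_used),
            "solver_times_s": list(self.solver_times),
            "boundary_mode": self.boundary.mode,
            "baseline_mode": self.baseline_mode,
            "d0": self.d0,
        }


def boundary_value(profiles: ProfileSeries, y_lb: float, time: float) -> float:
    """Noise-reduced boundary intensity: the mean of the profile value at the
    pixel nearest ``y_lb`` and its 5 lower and 5 higher neighbours."""
    i = int(np.argmin(np.abs(profiles.y_um - y_lb)))
    if i < 5 or i > profiles.y_um.size - 6:
        raise ValueError(
            f"lower boundary at pixel {i} needs 5 pixels on each side for the 11-point average"
        )
    j = int(np.argmin(np.abs(profiles.times_s - time)))
    return float(profiles.values[j, i - 5 : i + 6].mean())


def classify_boundary_shape(t1: float, I1: float, t2: float, I2: float) -> BoundaryMode:
    """Classify the early boundary rise.

    Growth from zero through (t1, I1), (t2, I2) is concave iff
    I2/I1 < t2/t1 (the saturating-exponential case); linear or convex growth
    (ratio ≥ t2/t1, tie included) cannot be captured by the saturating law
    and selects the all-spline boundary.
    """
    if not (0 < t1 < t2):
        raise ValueError("need 0 < t1 < t2")
    if I1 <= 0 or I2 <= 0:
        warnings.warn("non-positive boundary intensity; saturating-exponential fit not possible")
        return "all_spline"
    return "exp_then_spline" if I2 / I1 < t2 / t1 else "all_spline"


def fit_eq1(t1: float, I1: float, t2: float, I2: float) -> tuple:
    """Exact two-point fit of I(t) = I_inf * (1 - exp(-beta t)).

    For t2 = 2 t1 the closed form exp(-beta t1) = I2/I1 - 1 applies;
    otherwise beta solves a bracketed 1D root problem on [1e-8, 1] s⁻¹.
    Saturated data (I2 <= I1) pin beta at the top of the bracket.
    """
    if I1 <= 0 or I2 <= 0:
        raise ValueError("boundary intensities must be positive")
    beta_lo, beta_hi = 1e-8, 1.0
    if I2 <= I1:
        warnings.warn("boundary already saturated between t1 and t2; beta capped at bracket top")
        beta = beta_hi
        i_inf = I1 / -math.expm1(-beta * t1)
        return i_inf, beta
    if abs(t2 - 2.0 * t1) < 1e-9 * t1:
        x = I2 / I1 - 1.0
        if not (0.0 < x < 1.0):
            raise ValueError("inputs are not concave growth from zero")
        beta = -math.log(x) / t1
    else:
        def f(b):
            return I1 * -math.expm1(-b * t2) - I2 * -math.expm1(-b * t1)

        if f(beta_lo) * f(beta_hi) > 0:
            raise ValueError("no saturating-exponential fit in the beta bracket")
        beta = brentq(f, beta_lo, beta_hi, rtol=1e-12, maxiter=200)
    i_inf = I1 / -math.expm1(-beta * t1)
    return i_inf, beta


def build_boundary_function(profiles: ProfileSeries, geometry: GelGeometry) -> BoundaryFunction:
    """Construct the lower Dirichlet boundary from measured profiles.

    Boundary values are 11-point averages at the lower fit boundary at each
    measurement time; the shape of the first two fixes the mode.
    """
    times = profiles.times_s
    if times.size < 2:
        raise ValueError("need at least 2 time points to build a boundary function")
    values = np.array([boundary_value(profiles, geometry.y_lower_boundary, t) for t in times])
    t1, t2 = float(times[0]), float(times[1])
    I1, I2 = float(values[0]), float(values[1])
    if I1 > 0 and I2 > 0:
        mode = classify_boundary_shape(t1, I1, t2, I2)
    else:
        warnings.warn("non-positive early boundary values; falling back to all-spline mode")
        mode = "all_spline"
    if mode == "exp_then_spline":
        i_inf, beta = fit_eq1(t1, I1, t2, I2)
        knots = np.column_stack([times[1:], values[1:]])
        return BoundaryFunction(mode=mode, knots=knots, i_inf=i_inf, beta=beta)
    knots = np.column_stack([times, values])
    return BoundaryFunction(mode="all_spline", knots=knots)


def solve_crank_nicolson(
    D: float,
    boundary: BoundaryFunction,
    grid: FitGrid,
    output_times: Sequence[float],
    rannacher_substeps: int = 2,
) -> ProfileSeries:
    """Forward model: field on the fit grid at the requested times.

    Zero initial condition at t = 0 (drug addition), Dirichlet lower
    boundary from ``boundary``, sink (zero) upper boundary. Output times are
    rounded to the nearest solver step (≤ dt/2 = 15 s alignment error).
    """
    if D <= 0:
        raise ValueError("diffusion coefficient must be positive")
    steps = [int(round(t / grid.dt)) for t in output_times]
    out = crank_nicolson_1d(
        D, grid.dy, grid.n_nodes, grid.dt, boundary, steps, rannacher_substeps=rannacher_substeps
    )
    return ProfileSeries(
        y_um=grid.y_nodes.copy(),
        values=out,
        times_s=grid.dt * np.asarray(steps, dtype=float),
        units="au",
    )


def select_fit_timepoints(
    profiles: ProfileSeries,
    geometry: GelGeometry,
    sink_fraction: float = 0.02,
    presence_fraction: float = 0.05,
    presence_distance_um: float = 1000.0,
) -> tuple:
    """Select the two earliest measurement times suitable for fitting.

    A time qualifies when (i) the mean baseline-corrected intensity over the
    final 100 µm of the fit interval is below ``sink_fraction`` of that
    profile's maximum (the sink condition still holds), and (ii) the profile
    exceeds ``presence_fraction`` of its maximum somewhere more than
    ``presence_distance_um`` beyond the lower boundary (enough developed
    gradient to constrain D).
    """
    y = profiles.y_um
    lo = geometry.y_lower_boundary
    hi = geometry.y_upper_boundary
    sel = (y >= lo) & (y <= hi)
    sink_sel = sel & (y > hi - 100.0)
    far_sel = sel & (y > lo + presence_distance_um)
    qualifying, diagnostics = [], []
    for j, t in enumerate(profiles.times_s):
        prof = profiles.values[j]
        peak = prof[sel].max() if sel.any() else 0.0
        if peak <= 0:
            diagnostics.append((float(t), "no signal in fit interval"))
            continue
        sink_ok = prof[sink_sel].mean() < sink_fraction * peak
        presence_ok = bool((prof[far_sel] > presence_fraction * peak).any())
        if sink_ok and presence_ok:
            qualifying.append(float(t))
        else:
            reasons = []
            if not sink_ok:
                reasons.append("sink-end intensity too high")
            if not presence_ok:
                reasons.append(f"profile not developed beyond {presence_distance_um:g} µm")
            diagnostics.append((float(t), "; ".join(reasons)))
    if len(qualifying) < 2:
        detail = "; ".join(f"t={t:g}s: {r}" for t, r in diagnostics)
        raise ValueError(f"fewer than 2 time points qualify for fitting ({detail})")
    return qualifying[0], qualifying[1]


def _sample_at_nodes(profiles: ProfileSeries, grid: FitGrid) -> np.ndarray:
    """Measured values at the grid nodes (nearest pixel, half-pixel tolerance)."""
    idx = np.argmin(np.abs(profiles.y_um[None, :] - grid.y_nodes[:, None]), axis=1)
    pixel = np.median(np.diff(profiles.y_um))
    off = np.abs(profiles.y_um[idx] - grid.y_nodes)
    if off.max() > 0.51 * pixel:
        raise ValueError("fit-grid nodes do not lie on the measured pixel lattice")
    return profiles.values[:, idx]


def _penetration_d0(y_rel: np.ndarray, prof: np.ndarray, t_a: float) -> float:
    """Initial guess from the half-maximum penetration depth, D ≈ x50²/(4 t)."""
    peak = prof.max()
    if peak <= 0:
        return 300.0
    below = np.nonzero(prof < 0.5 * peak)[0]
    if below.size == 0:
        return 300.0
    x50 = max(y_rel[below[0]], y_rel[1])
    return float(x50**2 / (4.0 * t_a))


def fit_diffusion_coefficient(
    measured: ProfileSeries,
    boundary: BoundaryFunction,
    grid: FitGrid,
    d0: Optional[float] = None,
    max_iterations: int = 200,
    rel_sse_tol: float = 1e-6,
    lm_lambda0: float = 1e-3,
) -> DiffusionFit:
    """Levenberg–Marquardt fit of D to two measured profiles.

    The joint sum of squared residuals over both time points between the
    Crank–Nicolson prediction and the measurement (at the grid nodes) is
    minimized over the single parameter log D (keeping D positive). Damping
    starts at 1e-3, ×10 on a rejected step, ÷10 on an accepted one;
    convergence is declared when the relative SSE change between accepted
    iterations falls below 1e-6.
    """
    if measured.times_s.size != 2:
        raise ValueError("fit expects exactly two measured time points")
    data = _sample_at_nodes(measured, grid)
    if np.allclose(data, 0.0):
        raise ValueError("measured profiles are identically zero; nothing to fit")
    times = tuple(float(t) for t in measured.times_s)
    solver_times = tuple(grid.round_time(t) for t in times)

    def residuals(theta: float) -> np.ndarray:
        pred = solve_crank_nicolson(math.exp(theta), boundary, grid, solver_times)
        return (pred.values - data).ravel()

    if d0 is None:
        d0 = _penetration_d0(grid.y_nodes - grid.y_nodes[0], data[0], times[0])
    d0 = float(np.clip(d0, 1e-3, 1e6))
    theta = math.log(d0)
    r = residuals(theta)
    sse = float(r @ r)
    lam = lm_lambda0
    history = [sse]
    converged = False
    n_iter = 0
    h = 1e-4
    for n_iter in range(1, max_iterations + 1):
        J = (residuals(theta + h) - r) / h
        g = float(J @ r)
        H = float(J @ J)
        if H <= 0:
            break
        accepted = False
        sse_new = sse
        while lam < 1e14:
            step = -g / (H * (1.0 + lam))
            r_new = residuals(theta + step)
            sse_new = float(r_new @ r_new)
            if sse_new <= sse:
                theta += step
                r = r_new
                lam = max(lam / 10.0, 1e-12)
                accepted = True
                break
            lam *= 10.0
        if not accepted:
            converged = True  # no descent direction improves: at the optimum
            break
        rel_change = abs(sse - sse_new) / max(sse, 1e-300)
        sse = sse_new
        history.append(sse)
        if rel_change < rel_sse_tol:
            converged = True
            break
    return DiffusionFit(
        d_app=math.exp(theta),
        sse=sse,
        n_iterations=n_iter,
        converged=converged,
        times_used=times,
        solver_times=solver_times,
        boundary=boundary,
        grid=grid,
        baseline_mode=measured.baseline_mode,
        d0=d0,
        sse_history=history,
    )


def estimate_diffusion_coefficient(
    profiles: ProfileSeries,
    geometry: GelGeometry,
    pixel_size_um: Optional[float] = None,
    d0: Optional[float] = None,
    **select_kwargs,
) -> DiffusionFit:
    """Full inverse pipeline on baseline-corrected profiles: boundary
    construction, fit-time selection, and the LM fit."""
    if profiles.baseline_mode is None:
        raise ValueError("profiles must be baseline-corrected first")
    if pixel_size_um is None:
        pixel_size_um = float(np.median(np.diff(profiles.y_um)))
    grid = FitGrid.from_geometry(geometry, pixel_size_um)
    boundary = build_boundary_function(profiles, geometry)
    t_a, t_b = select_fit_timepoints(profiles, geometry, **select_kwargs)
    keep = np.isin(profiles.times_s, [t_a, t_b])
    measured = ProfileSeries(
        y_um=profiles.y_um,
        values=profiles.values[keep],
        times_s=profiles.times_s[keep],
        units=profiles.units,
        baseline_mode=profiles.baseline_mode,
    )
    return fit_diffusion_coefficient(measured, boundary, grid, d0=d0)
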