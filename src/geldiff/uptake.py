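"""Intracellular uptake kinetics and apparent cell permeability.

Zone-averaged intracellular concentrations grow linearly with time; their
slope is the zone uptake rate (µM/min). Plotting uptake rates against the
local gel concentration at 60, 120 and 180 min yields, by linear
regression, the overall transport rate constant k_cell (min⁻¹), and the
apparent permeability of a spherical cell follows as

    P_cell = k_cell · (V/A) / 60 = k_cell · r / (3 · 60)    [µm/s]
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cells import ANALYSIS_SPAN_UM, ZONE_WIDTH_UM, Cell, assign_zone
from .imaging import CalibrationCurve, ProfileSeries, to_concentration

__all__ = [
    "RateFit",
    "ZoneSeries",
    "UptakeResult",
    "uptake_rate",
    "zone_gel_concentration",
    "transport_rate_constant",
    "cell_permeability",
    "stokes_einstein_scale",
    "water_viscosity_pa_s",
    "analyze_uptake",
]

DEFAULT_UPTAKE_TIMES_S = (3600.0, 7200.0, 10800.0)  # 60, 120, 180 min


@dataclass(frozen=True)
class RateFit:
    """Ordinary least-squares slope with its diagnostics."""

    slope: float
    intercept: float
    stderr: float
    r_squared: float
    n: int


@dataclass
class ZoneSeries:
    """Zone-aggregated kinetics: mean intracellular concentration over time
    plus the local gel concentration at the regression times."""

    zone_index: int
    times_min: np.ndarray
    cell_conc_uM: np.ndarray
    gel_conc_uM: Dict[float, float]  # time_min -> µM
    n_cells: int


@dataclass
class UptakeResult:
    zone_rates: Dict[int, RateFit]
    k_cell: RateFit  # slope in min⁻¹
    p_cell_um_per_s: float
    cell_radius_um: float
    times_used_min: tuple
    zones: Dict[int, ZoneSeries] = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        return {
            "k_cell_per_min": self.k_cell.slope,
            "k_cell_stderr": self.k_cell.stderr,
            "p_cell_um_per_s": self.p_cell_um_per_s,
            "cell_radius_um": self.cell_radius_um,
            "times_used_min": list(self.times_used_min),
            "zone_uptake_rates_uM_per_min": {
                str(z): {"slope": r.slope, "stderr": r.stderr, "r_squared": r.r_squared}
                for z, r in self.zone_rates.items()
            },
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _ols(x: np.ndarray, y: np.ndarray) -> RateFit:
    res = stats.linregress(x, y)
    r2 = float(res.rvalue**2) if np.std(y) > 0 else 1.0
    return RateFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        stderr=float(res.stderr),
        r_squared=r2,
        n=x.size,
    )


def uptake_rate(times_min, conc_uM) -> RateFit:
    """Zone uptake rate: OLS slope of intracellular concentration vs time
    (µM/min), intercept free."""
    t = np.asarray(times_min, dtype=float)
    c = np.asarray(conc_uM, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 time points for an uptake rate")
    return _ols(t, c)


def zone_gel_concentration(
    profiles: ProfileSeries, zone_index: int, time_s: float,
    zone_width_um: float = ZONE_WIDTH_UM,
) -> float:
    """Mean gel concentration (µM) over a zone's axial interval at ``time_s``.

    Profiles must already be in concentration units; times between frames
    are linearly interpolated.
    """
    if profiles.units != "uM":
        raise ValueError("profiles must be in concentration units (µM)")
    prof = profiles.at_time(time_s)
    lo, hi = zone_index * zone_width_um, (zone_index + 1) * zone_width_um
    sel = (profiles.y_um >= lo) & (profiles.y_um < hi)
    if not sel.any():
        raise ValueError(f"zone {zone_index} lies outside the profile range")
    return float(prof[sel].mean())


def transport_rate_constant(uptake_rates_uM_per_min, gel_concs_uM) -> RateFit:
    """k_cell: OLS slope of uptake rate vs gel concentration across all
    (zone, time) pairs, intercept free."""
    u = np.asarray(uptake_rates_uM_per_min, dtype=float)
    c = np.asarray(gel_concs_uM, dtype=float)
    if u.size < 3:
        raise ValueError("need at least 3 (concentration, uptake) pairs")
    if np.ptp(c) == 0:
        raise ValueError("gel concentrations must vary")
    return _ols(c, u)


def cell_permeability(k_cell_per_min: float, radius_um: float) -> float:
    """Apparent cell permeability P_cell = k_cell·r/3/60 (µm/s), treating the
    cell as a sphere so V/A = r/3."""
    if radius_um <= 0:
        raise ValueError("cell radius must be positive")
    if k_cell_per_min < 0:
        raise ValueError("k_cell must be non-negative")
    return k_cell_per_min * radius_um / (3.0 * 60.0)


def water_viscosity_pa_s(temperature_K: float) -> float:
    """Vogel-type correlation for the dynamic viscosity of liquid water,
    η(T) = 2.414e-5 · 10^(247.8/(T−140)) Pa·s."""
    if not (273.15 <= temperature_K <= 373.15):
        raise ValueError("temperature outside the liquid-water range")
    return 2.414e-5 * 10.0 ** (247.8 / (temperature_K - 140.0))


def stokes_einstein_scale(d1_um2_per_s: float, t1_K: float, t2_K: float) -> float:
    """Rescale a free diffusion coefficient between temperatures via
    Stokes–Einstein: D ∝ T/η(T)."""
    if d1_um2_per_s <= 0:
        raise ValueError("diffusion coefficient must be positive")
    return (
        d1_um2_per_s
        * (t2_K / t1_K)
        * (water_viscosity_pa_s(t1_K) / water_viscosity_pa_s(t2_K))
    )


def analyze_uptake(
    cells: Sequence[Cell],
    gel_profiles_uM: ProfileSeries,
    calibration: CalibrationCurve,
    times_s: Sequence[float] = DEFAULT_UPTAKE_TIMES_S,
    frame_times_s: Optional[np.ndarray] = None,
    cell_radius_um: Optional[float] = None,
    subtract_gel_background: bool = True,
) -> UptakeResult:
    """Full uptake analysis from measured cells and a cell-free gel profile.

    Cellular DOX traces are converted to concentrations with the
    calibration line, averaged per 250 µm zone, and regressed against time
    to give zone uptake rates; rates against zone gel concentrations at
    ``times_s`` give k_cell, and the mean detected cell radius (or an
    override) gives P_cell.

    ``subtract_gel_background`` removes the local gel concentration from
    each zone's cellular trace before the time regression: the cell mask
    sits inside fluorescent gel, so its raw mean reports intracellular plus
    matrix signal.
    """
    if frame_times_s is None:
        frame_times_s = gel_profiles_uM.times_s
    frame_times_s = np.asarray(frame_times_s, dtype=float)
    analyzed = [c for c in cells if assign_zone(c).in_analysis]
    if not analyzed:
        raise ValueError("no cells within the analysis span")
    if cell_radius_um is None:
        cell_radius_um = float(np.mean([c.radius_um for c in analyzed]))

    by_zone: Dict[int, list] = {}
    for c in analyzed:
        by_zone.setdefault(assign_zone(c).zone_index, []).append(c)

    times_min = tuple(t / 60.0 for t in times_s)
    # concentration-vs-time regression uses the full course up to the last
    # gel-concentration timepoint (the experiment runs exactly that long)
    trace_sel = frame_times_s <= max(times_s) + 1e-9
    trace_times_min = frame_times_s[trace_sel] / 60.0

    zones: Dict[int, ZoneSeries] = {}
    zone_rates: Dict[int, RateFit] = {}
    pairs_u, pairs_c = [], []
    for z, zcells in sorted(by_zone.items()):
        traces = np.stack([c.traces["dox"] for c in zcells])[:, trace_sel]
        conc, _ = to_concentration(traces.mean(axis=0), calibration)
        gel = {
            tm: zone_gel_concentration(gel_profiles_uM, z, ts)
            for tm, ts in zip(times_min, times_s)
        }
        if subtract_gel_background:
            local = np.array(
                [zone_gel_concentration(gel_profiles_uM, z, ts) for ts in frame_times_s[trace_sel]]
            )
            conc = conc - local
        fit = uptake_rate(trace_times_min, conc)
        zones[z] = ZoneSeries(
            zone_index=z,
            times_min=trace_times_min,
            cell_conc_uM=conc,
            gel_conc_uM=gel,
            n_cells=len(zcells),
        )
        zone_rates[z] = fit
        for tm in times_min:
            pairs_u.append(fit.slope)
            pairs_c.append(gel[tm])

    k_fit = transport_rate_constant(pairs_u, pairs_c)
    k = max(k_fit.slope, 0.0)
    return UptakeResult(
        zone_rates=zone_rates,
        k_cell=k_fit,
        p_cell_um_per_s=cell_permeability(k, cell_radius_um),
        cell_radius_um=cell_radius_um,
        times_used_min=times_min,
        zones=zones,
    )
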