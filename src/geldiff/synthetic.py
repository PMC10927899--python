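"""Ground-truthed synthetic chip experiments.

Emulates the drug-diffusion/uptake chip: a 3 mm hydrogel channel imaged in
three channels (DOX fluorescence, NucBlue nuclear stain, DIC) while drug
diffuses in from a donor reservoir whose concentration saturates
exponentially, with a sink acceptor reservoir at the far end. Cells placed
in the gel accumulate drug proportionally to the local gel concentration
(dC_cell/dt = k_cell · C_gel) while their nuclear-stain signal decays with
accumulated intracellular drug. The generator works on a grid finer in
space and time than the fitting grid, so inverse fits on the coarse grid
are a genuine test rather than an inverse crime.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._pde import crank_nicolson_1d
from .imaging import CalibrationCurve, ImageSeries, ProfileSeries, write_image_series

__all__ = [
    "SimulationParams",
    "GroundTruth",
    "simulate_profiles",
    "simulate_experiment",
    "write_experiment",
]


@dataclass
class SimulationParams:
    """Knobs of the synthetic chip experiment.

    Defaults mirror the laboratory protocol: a 3 mm gel imaged at
    1.250339 µm/pixel every 5 min for 3 h with a 5 min lag between drug
    addition and the first frame, a 20 µM donor solution (intensity
    amplitude / calibration slope) saturating with a ~5 min time constant,
    and HepG2-like cells of radius 9.9 ± 0.7 µm taking up drug at
    0.016 min⁻¹.
    """

    d_true: float = 300.0  # µm²/s
    boundary_i_inf: float = 10000.0  # a.u. above background at the donor interface
    boundary_beta: float = 1.0 / 300.0  # 1/s; np.inf gives a step boundary
    gel_length_um: float = 3000.0
    pixel_size_um: float = 1.250339
    frame_interval_s: float = 300.0
    n_frames: int = 37
    t_lag_s: float = 300.0
    noise_sd: float = 50.0  # a.u., additive Gaussian detector noise
    n_cells: int = 0
    cell_radius_mean_um: float = 9.9
    cell_radius_sd_um: float = 0.7
    k_cell_true_per_min: float = 0.016
    nucblue_decay_coupling: float = 2.5e-4  # fraction per µM·min of accumulated drug
    calibration_slope: float = 500.0  # a.u. per µM
    calibration_intercept: float = 100.0  # a.u.
    seed: int = 0
    image_width_um: float = 1000.0
    nucblue_amplitude: float = 30000.0  # a.u. peak nuclear stain at t = 0
    nucblue_background: float = 200.0  # a.u. diffuse stain background
    dic_level: float = 30000.0  # a.u. background of the DIC channel
    cell_positions_um: Optional[Sequence[Tuple[float, float]]] = None  # explicit (x, y)

    def __post_init__(self):
        if self.d_true <= 0:
            raise ValueError("d_true must be positive")
        if self.gel_length_um <= 0:
            raise ValueError("gel_length_um must be positive")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_cells < 0:
            raise ValueError("n_cells must be non-negative")
        if self.boundary_beta <= 0:
            raise ValueError("boundary_beta must be positive (np.inf allowed)")
        if self.t_lag_s <= 0:
            raise ValueError("t_lag_s must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def donor_conc_inf_uM(self) -> float:
        return self.boundary_i_inf / self.calibration_slope

    @property
    def frame_times_s(self) -> np.ndarray:
        return self.t_lag_s + self.frame_interval_s * np.arange(self.n_frames)

    @property
    def calibration(self) -> CalibrationCurve:
        return CalibrationCurve(
            slope=self.calibration_slope,
            intercept=self.calibration_intercept,
            r_squared=1.0,
            valid_range_uM=(0.0, max(self.donor_conc_inf_uM, 1.0)),
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["cell_positions_um"] is not None:
            d["cell_positions_um"] = [list(p) for p in d["cell_positions_um"]]
        if math.isinf(d["boundary_beta"]):
            d["boundary_beta"] = "inf"
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationParams":
        d = dict(d)
        if d.get("boundary_beta") == "inf":
            d["boundary_beta"] = np.inf
        if d.get("cell_positions_um") is not None:
            d["cell_positions_um"] = [tuple(p) for p in d["cell_positions_um"]]
        return cls(**d)


@dataclass
class GroundTruth:
    """Everything needed to score downstream analyses of a synthetic run."""

    params: SimulationParams
    cell_table: pd.DataFrame  # id, x_um, y_um, radius_um
    boundary_times_s: np.ndarray
    boundary_conc_uM: np.ndarray  # realized donor-interface concentration
    cell_conc_uM: np.ndarray  # (n_frames, n_cells) intracellular concentration

    def to_manifest(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "cells": self.cell_table.to_dict(orient="list"),
            "boundary_times_s": self.boundary_times_s.tolist(),
            "boundary_conc_uM": self.boundary_conc_uM.tolist(),
            "cell_conc_uM": self.cell_conc_uM.tolist(),
        }

    @classmethod
    def from_manifest(cls, d: dict) -> "GroundTruth":
        return cls(
            params=SimulationParams.from_dict(d["params"]),
            cell_table=pd.DataFrame(d["cells"]),
            boundary_times_s=np.asarray(d["boundary_times_s"], dtype=float),
            boundary_conc_uM=np.asarray(d["boundary_conc_uM"], dtype=float),
            cell_conc_uM=np.asarray(d["cell_conc_uM"], dtype=float),
        )


def _donor_boundary(params: SimulationParams):
    """Donor-interface concentration vs time, C_inf·(1 − e^(−βt))."""
    c_inf = params.donor_conc_inf_uM
    beta = params.boundary_beta
    if math.isinf(beta):
        return lambda t: c_inf if np.ndim(t) == 0 and t > 0 else c_inf * (np.asarray(t) > 0)
    return lambda t: c_inf * -np.expm1(-beta * np.asarray(t))


def _fine_fields(params: SimulationParams, times: np.ndarray, n_accumulate: int = 0):
    """Concentration field (µM) on the pixel lattice at the requested times.

    The generating grid uses the native pixel spacing (10× finer than the
    fitting grid) and a time step ≤ 7.5 s (≥ 4× finer than the 30 s fitting
    step), aligned so every requested time is an integer number of steps.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0 or np.any(times <= 0) or np.any(np.diff(times) <= 0):
        raise ValueError("times must be positive and strictly increasing")
    n_nodes = int(round(params.gel_length_um / params.pixel_size_um)) + 1
    dt = 7.5
    # shrink dt so all requested times land exactly on steps
    while any(abs(t / dt - round(t / dt)) > 1e-9 for t in times) and dt > 0.1:
        dt /= 2.0
    steps = [int(round(t / dt)) for t in times]
    return crank_nicolson_1d(
        params.d_true,
        params.pixel_size_um,
        n_nodes,
        dt,
        _donor_boundary(params),
        steps,
        n_accumulate=n_accumulate,
    )


def simulate_profiles(params: SimulationParams, times: Sequence[float]) -> ProfileSeries:
    """Noiseless axial intensity profiles at the requested times (s).

    Concentration from the fine-grid forward model, converted to intensity
    through the calibration line I = slope·C + intercept.
    """
    times = np.asarray(times, dtype=float)
    conc = _fine_fields(params, times)
    intensity = params.calibration_slope * conc + params.calibration_intercept
    n_nodes = conc.shape[1]
    y = params.pixel_size_um * np.arange(n_nodes)
    return ProfileSeries(y_um=y, values=intensity, times_s=times, units="au")


def _place_cells(params: SimulationParams, rng: np.random.Generator):
    """Radii and positions; rejection sampling keeps cells separated by at
    least the sum of their diameters unless positions are given explicitly."""
    n = params.n_cells
    radii = np.abs(rng.normal(params.cell_radius_mean_um, params.cell_radius_sd_um, size=n))
    radii = np.clip(radii, 1.0, None)
    L, W = params.gel_length_um, params.image_width_um
    if params.cell_positions_um is not None:
        pos = np.asarray(params.cell_positions_um, dtype=float)
        if pos.shape != (n, 2):
            raise ValueError("cell_positions_um must provide one (x, y) pair per cell")
        xs, ys = pos[:, 0], pos[:, 1]
        if np.any(ys - radii < 0) or np.any(ys + radii > L):
            raise ValueError("explicit cell positions exceed the gel bounds")
        return xs, ys, radii
    if n and np.any(2 * radii >= min(L, W)):
        raise ValueError("cells are too large to place inside the gel bounds")
    xs = np.empty(n)
    ys = np.empty(n)
    for i in range(n):
        for attempt in range(2000):
            x = rng.uniform(radii[i], W - radii[i])
            y = rng.uniform(radii[i], L - radii[i])
            if i == 0:
                break
            d2 = (xs[:i] - x) ** 2 + (ys[:i] - y) ** 2
            min_sep = 2.0 * (radii[:i] + radii[i])
            if np.all(d2 >= min_sep**2):
                break
        else:
            raise ValueError(
                f"could not place {n} cells without exceeding gel bounds or overlapping"
            )
        xs[i], ys[i] = x, y
    return xs, ys, radii


def _disk_indices(xc_px, yc_px, radius_px, shape):
    """Pixel rows/cols within ``radius_px`` of the center, plus distances."""
    ny, nx = shape
    r0 = max(int(math.floor(yc_px - radius_px)), 0)
    r1 = min(int(math.ceil(yc_px + radius_px)), ny - 1)
    c0 = max(int(math.floor(xc_px - radius_px)), 0)
    c1 = min(int(math.ceil(xc_px + radius_px)), nx - 1)
    rr, cc = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij")
    d2 = (rr - yc_px) ** 2 + (cc - xc_px) ** 2
    inside = d2 <= radius_px**2
    return rr[inside], cc[inside], np.sqrt(d2[inside])


def simulate_experiment(params: SimulationParams):
    """Render a full multi-channel synthetic time-lapse.

    Returns (ImageSeries, GroundTruth). Channels:

    * ``dox`` — gel gradient through the calibration line, plus a uniform
      disk (the whole cell, radius r) of added intensity tracking the
      accumulated intracellular concentration k_cell·∫C_gel dt;
    * ``nucblue`` — Gaussian-profile nuclei (radius 0.7 r, σ = r_nuc/2)
      whose amplitude decays as exp(−c·∫C_cell dt);
    * ``dic`` — uniform field with dark lines marking the gel interfaces.

    Per-pixel i.i.d. Gaussian noise of sd ``noise_sd`` is added to every
    channel and the result is quantized to 16-bit.
    """
    rng = np.random.default_rng(params.seed)
    times = params.frame_times_s
    conc, cum1, cum2 = _fine_fields(params, times, n_accumulate=2)
    ny = conc.shape[1]
    nx = int(round(params.image_width_um / params.pixel_size_um))
    px = params.pixel_size_um
    n_frames = params.n_frames
    slope, intercept = params.calibration_slope, params.calibration_intercept

    xs, ys, radii = _place_cells(params, rng)
    n_cells = params.n_cells
    cell_rows = np.clip(np.round(ys / px).astype(int), 0, ny - 1)
    k_per_s = params.k_cell_true_per_min / 60.0
    # C_cell(t) = k_cell ∫ C_gel dt ; accumulated exposure ∫ C_cell dt (µM·min)
    cell_conc = k_per_s * cum1[:, cell_rows] if n_cells else np.zeros((n_frames, 0))
    cell_exposure_uM_min = (k_per_s * cum2[:, cell_rows] / 60.0) if n_cells else np.zeros((n_frames, 0))

    cell_disks = []  # (rows, cols) of the full-cell disk, for the DOX channel
    nuc_disks = []  # (rows, cols, gaussian weight) for the NucBlue channel
    for i in range(n_cells):
        xc_px, yc_px, r_px = xs[i] / px, ys[i] / px, radii[i] / px
        rr, cc, _ = _disk_indices(xc_px, yc_px, r_px, (ny, nx))
        cell_disks.append((rr, cc))
        r_nuc = 0.7 * r_px
        rr, cc, dist = _disk_indices(xc_px, yc_px, r_nuc, (ny, nx))
        sigma = r_nuc / 2.0
        nuc_disks.append((rr, cc, np.exp(-(dist**2) / (2.0 * sigma**2))))

    def finalize(frame):
        if params.noise_sd > 0:
            frame = frame + rng.normal(0.0, params.noise_sd, size=frame.shape)
        return np.clip(np.rint(frame), 0, 65535).astype(np.uint16)

    dox = np.empty((n_frames, ny, nx), dtype=np.uint16)
    nucblue = np.empty_like(dox)
    dic = np.empty_like(dox)
    dic_base = np.full((ny, nx), params.dic_level)
    dic_base[0:2, :] = 0.2 * params.dic_level
    dic_base[-2:, :] = 0.2 * params.dic_level
    for k in range(n_frames):
        frame = np.repeat((slope * conc[k] + intercept)[:, None], nx, axis=1)
        for i, (rr, cc) in enumerate(cell_disks):
            frame[rr, cc] += slope * cell_conc[k, i]
        dox[k] = finalize(frame)

        frame = np.full((ny, nx), params.nucblue_background)
        for i, (rr, cc, w) in enumerate(nuc_disks):
            amp = params.nucblue_amplitude * math.exp(
                -params.nucblue_decay_coupling * cell_exposure_uM_min[k, i]
            )
            frame[rr, cc] += amp * w
        nucblue[k] = finalize(frame)

        dic[k] = finalize(dic_base.copy())

    series = ImageSeries(
        channels={"nucblue": nucblue, "dox": dox, "dic": dic},
        pixel_size_um=px,
        timestamps_s=times,
        t_lag_s=params.t_lag_s,
    )
    truth = GroundTruth(
        params=params,
        cell_table=pd.DataFrame(
            {"id": np.arange(n_cells), "x_um": xs, "y_um": ys, "radius_um": radii}
        ),
        boundary_times_s=times,
        boundary_conc_uM=np.asarray(_donor_boundary(params)(times), dtype=float),
        cell_conc_uM=cell_conc,
    )
    return series, truth


def write_experiment(series: ImageSeries, truth: GroundTruth, outdir) -> None:
    """Persist a synthetic run: per-channel TIFFs, manifest.json with the
    ground truth, and the noiseless profiles as profiles_true.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_image_series(series, outdir)
    (outdir / "manifest.json").write_text(json.dumps(truth.to_manifest(), indent=2))
    profs = simulate_profiles(truth.params, truth.params.frame_times_s)
    conc = (profs.values - truth.params.calibration_intercept) / truth.params.calibration_slope
    df = profs.to_dataframe()
    df["concentration_uM"] = conc.ravel()
    df.to_csv(outdir / "profiles_true.csv", index=False)
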