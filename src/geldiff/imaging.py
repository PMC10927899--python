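"""Image-series IO, gel geometry, axial profile extraction and calibration.

Conventions: the axial coordinate y is 0 at the donor-side gel interface and
increases toward the acceptor reservoir; timestamps are absolute seconds
since drug addition (they already include the lag time between adding the
donor solution and the first acquisition).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import tifffile
from scipy import stats

__all__ = [
    "ImageSeries",
    "GelGeometry",
    "ProfileSeries",
    "CalibrationCurve",
    "read_image_series",
    "write_image_series",
    "detect_gel_boundaries",
    "extract_profile",
    "baseline_correct",
    "fit_calibration",
    "to_concentration",
]

CHANNELS = ("nucblue", "dox", "dic")

# calibration lines flatter than this are rejected by the analysis pipeline
MIN_CALIBRATION_R2 = 0.97


@dataclass
class ImageSeries:
    """Time-ordered multi-channel 2D frames.

    channels maps channel name -> (T, Y, X) array. Row 0 is at the donor
    side of the field of view.
    """

    channels: Dict[str, np.ndarray]
    pixel_size_um: float
    timestamps_s: np.ndarray  # absolute, include t_lag
    t_lag_s: float

    def __post_init__(self):
        self.timestamps_s = np.asarray(self.timestamps_s, dtype=float)
        shapes = {name: arr.shape for name, arr in self.channels.items()}
        ref = next(iter(shapes.values()))
        for name, shp in shapes.items():
            if shp != ref:
                raise ValueError(f"channel {name!r} shape {shp} differs from {ref}")
        if ref[0] != self.timestamps_s.size:
            raise ValueError("number of timestamps must match frame count")
        if np.any(np.diff(self.timestamps_s) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if not (self.t_lag_s > 0 and self.timestamps_s[0] >= self.t_lag_s):
            raise ValueError("need timestamps[0] >= t_lag > 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")

    @property
    def n_frames(self) -> int:
        return self.timestamps_s.size

    @property
    def frame_shape(self) -> tuple:
        return next(iter(self.channels.values())).shape[1:]


@dataclass(frozen=True)
class GelGeometry:
    """Axial positions (µm) of the gel interfaces and the fit interval."""

    y_donor_interface: float
    y_acceptor_interface: float
    y_lower_boundary: float
    y_upper_boundary: float
    donor_at_low_y: bool = True

    def __post_init__(self):
        if not (
            self.y_donor_interface
            < self.y_lower_boundary
            < self.y_upper_boundary
            <= self.y_acceptor_interface
        ):
            raise ValueError(
                "need donor interface < lower boundary < upper boundary <= acceptor interface"
            )

    @property
    def gel_length_um(self) -> float:
        return self.y_acceptor_interface - self.y_donor_interface


@dataclass
class ProfileSeries:
    """Axial intensity (or concentration) profiles at multiple times."""

    y_um: np.ndarray  # uniform pixel lattice
    values: np.ndarray  # (T, n_y)
    times_s: np.ndarray
    units: str = "au"  # "au" or "uM"
    baseline_mode: Optional[str] = None

    def __post_init__(self):
        self.y_um = np.asarray(self.y_um, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.values.shape != (self.times_s.size, self.y_um.size):
            raise ValueError("values must have shape (n_times, n_y)")
        d = np.diff(self.y_um)
        if d.size and not np.allclose(d, d[0], rtol=1e-6):
            raise ValueError("y grid must be uniformly spaced")

    def at_time(self, time_s: float) -> np.ndarray:
        """Profile at ``time_s``, linearly interpolated between frames."""
        t = self.times_s
        if not (t[0] <= time_s <= t[-1]):
            raise ValueError(f"time {time_s} s outside measured range [{t[0]}, {t[-1]}]")
        j = int(np.searchsorted(t, time_s, side="right")) - 1
        if j == t.size - 1 or t[j] == time_s:
            return self.values[j].copy()
        w = (time_s - t[j]) / (t[j + 1] - t[j])
        return (1 - w) * self.values[j] + w * self.values[j + 1]

    def to_dataframe(self) -> pd.DataFrame:
        col = "conc_uM" if self.units == "uM" else "intensity"
        t = np.repeat(self.times_s, self.y_um.size)
        y = np.tile(self.y_um, self.times_s.size)
        return pd.DataFrame({"time_s": t, "y_um": y, col: self.values.ravel()})

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ProfileSeries":
        col = "conc_uM" if "conc_uM" in df.columns else "intensity"
        times = np.unique(df["time_s"].to_numpy())
        y = np.unique(df["y_um"].to_numpy())
        piv = df.pivot_table(index="time_s", columns="y_um", values=col).to_numpy()
        return cls(y_um=y, values=piv, times_s=times, units="uM" if col == "conc_uM" else "au")

    @classmethod
    def from_csv(cls, path) -> "ProfileSeries":
        return cls.from_dataframe(pd.read_csv(path))


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear intensity-vs-concentration calibration, I = slope*C + intercept."""

    slope: float  # a.u. per µM
    intercept: float  # a.u.
    r_squared: float
    valid_range_uM: tuple

    def __post_init__(self):
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")
        if not (0.0 <= self.r_squared <= 1.0):
            raise ValueError("R² must lie in [0, 1]")

    @property
    def acceptable(self) -> bool:
        """Linearity criterion for use in the pipeline (R² > 0.97)."""
        return self.r_squared > MIN_CALIBRATION_R2

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "slope_au_per_uM": self.slope,
                    "intercept_au": self.intercept,
                    "r_squared": self.r_squared,
                    "valid_range_uM": list(self.valid_range_uM),
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path) -> "CalibrationCurve":
        d = json.loads(Path(path).read_text())
        return cls(
            slope=d["slope_au_per_uM"],
            intercept=d["intercept_au"],
            r_squared=d["r_squared"],
            valid_range_uM=tuple(d["valid_range_uM"]),
        )


def write_image_series(series: ImageSeries, outdir) -> None:
    """One multi-page TIFF per channel (TYX), plus series metadata JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, arr in series.channels.items():
        tifffile.imwrite(outdir / f"{name}.tif", arr)
    meta = {
        "pixel_size_um": series.pixel_size_um,
        "timestamps_s": series.timestamps_s.tolist(),
        "t_lag_s": series.t_lag_s,
        "channels": sorted(series.channels),
    }
    (outdir / "series.json").write_text(json.dumps(meta, indent=2))


def read_image_series(
    path,
    channel_map: Optional[Mapping[str, Union[str, int]]] = None,
    metadata: Optional[Mapping] = None,
) -> ImageSeries:
    """Read a series from a directory of per-channel TIFFs or a single stack.

    For a directory, ``channel_map`` maps channel names to file names
    (default ``<name>.tif``) and metadata defaults to ``series.json`` in the
    directory. For a single TIFF the stack must be (T, C, Y, X) or
    (T, Y, X); ``channel_map`` then maps names to channel indices.
    Metadata must provide ``pixel_size_um``, ``t_lag_s`` and either
    ``timestamps_s`` or ``frame_interval_s``.
    """
    path = Path(path)
    metadata = dict(metadata or {})
    channels: Dict[str, np.ndarray] = {}
    if path.is_dir():
        if not metadata and (path / "series.json").exists():
            metadata = json.loads((path / "series.json").read_text())
        names = channel_map or {
            n: f"{n}.tif" for n in metadata.get("channels", CHANNELS) if (path / f"{n}.tif").exists()
        }
        for name, fname in names.items():
            f = path / str(fname)
            if not f.exists():
                raise FileNotFoundError(f"channel {name!r}: no file {f}")
            arr = tifffile.imread(f)
            channels[name] = np.atleast_3d(arr) if arr.ndim >= 3 else arr[None]
    else:
        stack = tifffile.imread(path)
        if stack.ndim == 3:
            name = next(iter(channel_map)) if channel_map else "dox"
            channels[name] = stack
        elif stack.ndim == 4:
            cmap = channel_map or {n: i for i, n in enumerate(CHANNELS[: stack.shape[1]])}
            for name, idx in cmap.items():
                channels[name] = stack[:, int(idx)]
        else:
            raise ValueError(f"unsupported stack dimensionality {stack.ndim}")
    shapes = {n: a.shape for n, a in channels.items()}
    ref = next(iter(shapes.values()))
    for n, s in shapes.items():
        if s != ref:
            raise ValueError(f"inconsistent frame shapes: channel {n!r} is {s}, expected {ref}")
    n_frames = ref[0]
    if "timestamps_s" in metadata:
        timestamps = np.asarray(metadata["timestamps_s"], dtype=float)
    elif "frame_interval_s" in metadata:
        t_lag = float(metadata["t_lag_s"])
        timestamps = t_lag + float(metadata["frame_interval_s"]) * np.arange(n_frames)
    else:
        raise ValueError("metadata must supply timestamps_s or frame_interval_s")
    return ImageSeries(
        channels=channels,
        pixel_size_um=float(metadata["pixel_size_um"]),
        timestamps_s=timestamps,
        t_lag_s=float(metadata["t_lag_s"]),
    )


def detect_gel_boundaries(
    series: ImageSeries,
    overrides: Optional[Mapping[str, float]] = None,
    lower_boundary_offset_um: float = 150.0,
    min_contrast: float = 4.0,
) -> GelGeometry:
    """Locate the gel interfaces from the DIC channel (dark transverse lines).

    ``overrides`` may supply any of the GelGeometry fields and win over
    detection; supplying both interfaces makes the DIC channel optional.
    The default fit interval starts ``lower_boundary_offset_um`` inside the
    donor interface (avoiding the irregular region near the donor solution)
    and ends at the acceptor interface. All positions snap to the pixel
    lattice.
    """
    overrides = dict(overrides or {})
    px = series.pixel_size_um

    def snap(v):
        return round(v / px) * px

    have_both = "y_donor_interface" in overrides and "y_acceptor_interface" in overrides
    if not have_both:
        if "dic" not in series.channels:
            raise ValueError(
                "no DIC channel and interfaces not overridden; supply "
                "y_donor_interface and y_acceptor_interface"
            )
        dic = series.channels["dic"][0].astype(float)
        prof = dic.mean(axis=1)
        med, sd = float(np.median(prof)), float(prof.std())
        if sd == 0:
            raise ValueError("DIC channel is featureless; supply geometry overrides")
        depth = (med - prof) / sd
        candidates = np.nonzero(depth > min_contrast)[0]
        if candidates.size < 2 or (candidates.max() - candidates.min()) < prof.size // 2:
            raise ValueError(
                "gel interfaces not detected with sufficient confidence in the DIC "
                "channel; supply geometry overrides"
            )
        half = (candidates.min() + candidates.max()) / 2.0
        low = candidates[candidates <= half]
        high = candidates[candidates > half]
        row_donor = int(low[np.argmax(depth[low])])
        row_accept = int(high[np.argmax(depth[high])])
        overrides.setdefault("y_donor_interface", row_donor * px)
        overrides.setdefault("y_acceptor_interface", row_accept * px)
    donor = snap(overrides["y_donor_interface"])
    accept = snap(overrides["y_acceptor_interface"])
    lower = snap(overrides.get("y_lower_boundary", donor + lower_boundary_offset_um))
    upper = snap(overrides.get("y_upper_boundary", accept))
    return GelGeometry(
        y_donor_interface=donor,
        y_acceptor_interface=accept,
        y_lower_boundary=lower,
        y_upper_boundary=upper,
    )


def extract_profile(
    series: ImageSeries,
    geometry: GelGeometry,
    channel: str = "dox",
    roi_width_um: float = 100.0,
    roi_center_x_um: Optional[float] = None,
    exclude_masks: Optional[Sequence[np.ndarray]] = None,
) -> ProfileSeries:
    """Mean intensity across a ``roi_width_um``-wide axial stripe, per y pixel.

    The stripe runs from the donor to the acceptor reservoir, centered
    transversely by default. y = 0 at the donor interface. ``exclude_masks``
    (boolean (Y, X) arrays, e.g. cell masks) removes pixels from the
    transverse average.
    """
    if channel not in series.channels:
        raise KeyError(f"channel {channel!r} not present (have {sorted(series.channels)})")
    stack = series.channels[channel].astype(float)
    px = series.pixel_size_um
    n_y, n_x = stack.shape[1:]
    width_px = max(1, int(round(roi_width_um / px)))
    if width_px > n_x:
        raise ValueError("ROI width exceeds image width")
    center = n_x / 2.0 if roi_center_x_um is None else roi_center_x_um / px
    x0 = int(round(center - width_px / 2.0))
    x0 = min(max(x0, 0), n_x - width_px)
    row0 = int(round(geometry.y_donor_interface / px))
    row1 = int(round(geometry.y_acceptor_interface / px))
    sub = stack[:, row0 : row1 + 1, x0 : x0 + width_px]
    if exclude_masks is not None:
        keep = np.ones(sub.shape[1:], dtype=bool)
        for m in exclude_masks:
            keep &= ~m[row0 : row1 + 1, x0 : x0 + width_px]
        weights = keep.astype(float)
        denom = weights.sum(axis=1)
        denom[denom == 0] = np.nan
        values = np.einsum("tyx,yx->ty", sub, weights) / denom
        # rows fully covered by masks fall back to the unmasked mean
        full = np.isnan(values)
        if full.any():
            plain = sub.mean(axis=2)
            values[full] = plain[full]
    else:
        values = sub.mean(axis=2)
    y = px * np.arange(row1 - row0 + 1)
    return ProfileSeries(y_um=y, values=values, times_s=series.timestamps_s.copy(), units="au")


def baseline_correct(profiles: ProfileSeries, mode: str = "far_segment") -> ProfileSeries:
    """Baseline (background) correction against the first (t = t_lag) frame.

    ``far_segment`` subtracts one scalar — the mean of the first profile over
    the final 100 µm of the gel (furthest from the donor); ``full_profile``
    subtracts the entire first profile pointwise. Negative values are kept:
    clipping would bias the least-squares fit.
    """
    if mode == "far_segment":
        seg = profiles.y_um >= profiles.y_um[-1] - 100.0
        baseline = float(profiles.values[0, seg].mean())
        corrected = profiles.values - baseline
    elif mode == "full_profile":
        corrected = profiles.values - profiles.values[0]
    else:
        raise ValueError(f"unknown baseline mode {mode!r}")
    return ProfileSeries(
        y_um=profiles.y_um.copy(),
        values=corrected,
        times_s=profiles.times_s.copy(),
        units=profiles.units,
        baseline_mode=mode,
    )


def fit_calibration(concentrations_uM, intensities_au) -> CalibrationCurve:
    """Ordinary least-squares intensity-vs-concentration line.

    Calibration lines in these gels are linear between about 1 and 20 µM;
    a fit is accepted into the pipeline only when R² > 0.97.
    """
    c = np.asarray(concentrations_uM, dtype=float)
    i = np.asarray(intensities_au, dtype=float)
    if c.size < 3:
        raise ValueError("need at least 3 calibration points")
    if np.unique(c).size < 2:
        raise ValueError("calibration concentrations must vary")
    res = stats.linregress(c, i)
    return CalibrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        valid_range_uM=(float(c.min()), float(c.max())),
    )


def to_concentration(intensity_au, curve: CalibrationCurve):
    """Invert the calibration line, C = (I - intercept)/slope.

    Returns (concentration_uM, out_of_range) where the flag marks values
    outside the calibrated range — above ~25 µM self-quenching makes the
    intensity–concentration relation sub-linear, so such conversions are
    unreliable rather than invalid.
    """
    arr = np.asarray(intensity_au, dtype=float)
    conc = (arr - curve.intercept) / curve.slope
    lo, hi = curve.valid_range_uM
    flag = (conc < lo) | (conc > hi)
    if np.isscalar(intensity_au) or arr.ndim == 0:
        return float(conc), bool(flag)
    return conc, flag
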