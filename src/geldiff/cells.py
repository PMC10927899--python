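"""Nucleus detection and single-cell intensity traces.

The segmentation follows the classic projection pipeline: maximum-intensity
projection of the NucBlue channel over the whole time series, global
threshold, binary dilation, watershed splitting of touching clusters, and
particle analysis. Cell positions are assumed static, so one projection-
derived ROI list serves every frame and both fluorescence channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.morphology import dilation, disk
from skimage.segmentation import watershed

from .imaging import ImageSeries

__all__ = [
    "Cell",
    "ZoneAssignment",
    "detect_nuclei",
    "measure_cell_intensities",
    "assign_zone",
    "relative_intensity",
    "cells_to_dataframe",
    "traces_to_dataframe",
]

ZONE_WIDTH_UM = 250.0
ANALYSIS_SPAN_UM = 2000.0


@dataclass
class Cell:
    """One detected nucleus with its (dilated) mask and per-frame traces."""

    id: int
    y_um: float  # centroid, gel frame (0 at donor interface)
    x_um: float
    area_um2: float  # dilated mask area
    pixels: tuple = field(repr=False)  # (rows, cols) index arrays of the mask
    traces: Dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    @property
    def radius_um(self) -> float:
        """Equivalent-circle radius of the projected (dilated) area."""
        return float(np.sqrt(self.area_um2 / np.pi))


@dataclass(frozen=True)
class ZoneAssignment:
    """250 µm axial bin, half-open [250k, 250(k+1)); zones 0–7 (0–2000 µm)
    are analyzed, cells beyond 2000 µm are flagged out-of-analysis."""

    zone_index: int
    bounds_um: tuple
    in_analysis: bool


def detect_nuclei(
    series: ImageSeries,
    threshold: Optional[float] = None,
    dilation_radius_px: int = 2,
    min_radius_um: float = 3.0,
    watershed_area_factor: float = 1.5,
) -> List[Cell]:
    """Segment nuclei on the max projection of the NucBlue channel.

    Otsu's threshold is used unless an explicit one is given; components
    larger than ``watershed_area_factor`` × the median component area are
    split by a distance-transform watershed (clusters of touching nuclei);
    components with equivalent radius below ``min_radius_um`` are discarded.
    Returns geometry-only cells (no traces) sorted by y position.
    """
    if "nucblue" not in series.channels:
        raise KeyError("series has no 'nucblue' channel")
    px = series.pixel_size_um
    proj = series.channels["nucblue"].max(axis=0).astype(float)
    if proj.max() <= proj.min():
        return []
    thr = float(threshold_otsu(proj)) if threshold is None else float(threshold)
    mask = proj > thr
    if not mask.any():
        return []
    if dilation_radius_px > 0:
        mask = dilation(mask, disk(dilation_radius_px))
    labels, n = ndi.label(mask)
    if n == 0:
        return []
    areas = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    median_area = float(np.median(areas))

    out_labels = np.zeros_like(labels)
    next_label = 1
    for lab in range(1, n + 1):
        comp = labels == lab
        if areas[lab - 1] > watershed_area_factor * median_area:
            dist = ndi.distance_transform_edt(comp)
            # peaks closer than ~the component's own equivalent radius are one
            # nucleus (plateau maxima of the distance transform), not a cluster
            equiv_r_px = np.sqrt(areas[lab - 1] / np.pi)
            min_dist = max(int(round(0.7 * equiv_r_px)), int(round(min_radius_um / px)), 1)
            peaks = peak_local_max(dist, labels=comp, min_distance=min_dist, exclude_border=False)
            if len(peaks) >= 2:
                markers = np.zeros_like(labels)
                for i, (r, c) in enumerate(peaks):
                    markers[r, c] = i + 1
                split = watershed(-dist, markers, mask=comp)
                for s in range(1, split.max() + 1):
                    out_labels[split == s] = next_label
                    next_label += 1
                continue
        out_labels[comp] = next_label
        next_label += 1

    cells: List[Cell] = []
    min_area_px = np.pi * (min_radius_um / px) ** 2
    for lab in range(1, next_label):
        rows, cols = np.nonzero(out_labels == lab)
        if rows.size < min_area_px:
            continue
        cells.append(
            Cell(
                id=0,
                y_um=float(rows.mean()) * px,
                x_um=float(cols.mean()) * px,
                area_um2=rows.size * px**2,
                pixels=(rows, cols),
            )
        )
    cells.sort(key=lambda c: (c.y_um, c.x_um))
    for i, c in enumerate(cells):
        c.id = i
    return cells


def measure_cell_intensities(
    series: ImageSeries, cells: Sequence[Cell], channels: Sequence[str] = ("nucblue", "dox")
) -> List[Cell]:
    """Mean intensity over each cell's dilated mask, per frame and channel.

    Traces are attached to the cells in place (and returned for chaining).
    """
    ny, nx = series.frame_shape
    for cell in cells:
        rows, cols = cell.pixels
        if rows.size == 0 or rows.max() >= ny or cols.max() >= nx or rows.min() < 0:
            raise ValueError(f"cell {cell.id} mask lies outside the image bounds")
        for ch in channels:
            if ch not in series.channels:
                raise KeyError(f"channel {ch!r} not present")
            stack = series.channels[ch]
            cell.traces[ch] = stack[:, rows, cols].mean(axis=1).astype(float)
    return list(cells)


def assign_zone(cell: Cell, zone_width_um: float = ZONE_WIDTH_UM,
                analysis_span_um: float = ANALYSIS_SPAN_UM) -> ZoneAssignment:
    """Axial zone of a cell; zone k covers [250k, 250(k+1)) from the donor."""
    y = cell.y_um
    if y < 0:
        raise ValueError("cell y position must be non-negative")
    k = int(np.floor(y / zone_width_um))
    return ZoneAssignment(
        zone_index=k,
        bounds_um=(k * zone_width_um, (k + 1) * zone_width_um),
        in_analysis=y < analysis_span_um,
    )


def relative_intensity(
    cells: Sequence[Cell], channel: str, t_ref_index: int = 0
) -> np.ndarray:
    """Zone-mean trace as a percentage of its value at the reference frame."""
    if not cells:
        raise ValueError("no cells in zone")
    traces = np.stack([c.traces[channel] for c in cells])
    mean = traces.mean(axis=0)
    ref = mean[t_ref_index]
    if ref <= 0:
        raise ValueError("reference intensity must be positive")
    return 100.0 * mean / ref


def cells_to_dataframe(cells: Sequence[Cell]) -> pd.DataFrame:
    rows = []
    for c in cells:
        z = assign_zone(c)
        rows.append(
            {
                "id": c.id,
                "x_um": c.x_um,
                "y_um": c.y_um,
                "area_um2": c.area_um2,
                "radius_um": c.radius_um,
                "zone": z.zone_index if z.in_analysis else -1,
            }
        )
    return pd.DataFrame(rows)


def traces_to_dataframe(cells: Sequence[Cell], times_s: np.ndarray) -> pd.DataFrame:
    rows = []
    for c in cells:
        for j, t in enumerate(times_s):
            row = {"cell_id": c.id, "time_s": float(t)}
            for ch, tr in c.traces.items():
                row[ch] = float(tr[j])
            rows.append(row)
    return pd.DataFrame(rows)
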