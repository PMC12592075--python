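"""3D detection of tdTomato-labelled PKD2L1+ cells and radial mapping.

Detection chain, applied to the cell channel of a two-channel stack:

1. per-slice min-max rescale to [0, 1] followed by CDF-based histogram
   equalization (256 bins, lowest occupied bin mapped to 0);
2. global binary threshold at 95% of the whole-stack maximum (ties are
   foreground);
3. 3D connected components (26-connectivity) with objects below 6000
   voxels removed (6000 itself is kept);
4. centroid extraction and in-plane distance to the canal centre of the
   nearest valid slice, then proximal (≤ 100 μm) / distal (≤ 230 μm) /
   outside zone classification and distance ECDFs.

Touching cells merge into a single component and are counted once; no
splitting is attempted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from statsmodels.distributions.empirical_distribution import ECDF

from .cc_geometry import EllipseFit

__all__ = [
    "DetectedCell",
    "ZoneSummary",
    "normalize_stack",
    "threshold_stack",
    "label_and_filter",
    "locate_cells",
    "classify_zones",
    "distance_ecdf",
    "detect_cells",
    "canal_centers_from_fits",
]

logger = logging.getLogger(__name__)

DEFAULT_MIN_VOXELS = 6000
DEFAULT_THRESHOLD_FRACTION = 0.95
DEFAULT_ZONE_BOUNDS_UM = (100.0, 230.0)


@dataclass
class DetectedCell:
    """One retained labelled object in the cell channel."""

    label: int
    x_um: float
    y_um: float
    z_um: float
    z_slice: int
    volume_voxels: int
    volume_um3: float
    distance_um: float = math.nan  # NaN when no canal reference in z-window
    zone: str | None = None  # proximal | distal | outside | None
    no_reference: bool = False


def _equalize_slice(sl: np.ndarray, bins: int) -> np.ndarray:
    """Histogram equalization via the normalized CDF with cdf-min subtraction.

    eq(v) = (CDF(v) − CDF_min) / (1 − CDF_min), so the lowest occupied
    intensity maps to 0 and the highest to 1.
    """
    hist, _ = np.histogram(sl, bins=bins, range=(0.0, 1.0))
    cdf = np.cumsum(hist) / sl.size
    occupied = np.flatnonzero(hist)
    cdf_min = cdf[occupied[0]]
    if cdf_min >= 1.0:
        return np.zeros_like(sl)
    lut = np.clip((cdf - cdf_min) / (1.0 - cdf_min), 0.0, 1.0)
    idx = np.minimum((sl * bins).astype(np.int64), bins - 1)
    return lut[idx].astype(sl.dtype)


def normalize_stack(stack: np.ndarray, bins: int = 256) -> np.ndarray:
    """Per-slice min-max rescale then histogram equalization, to [0, 1].

    Slices are processed independently.  A constant slice has no defined
    rescale; it is set to all zeros with a logged warning.
    """
    stack = np.asarray(stack, dtype=np.float64)
    if stack.ndim != 3 or stack.size == 0:
        raise ValueError("expected a non-empty (z, y, x) stack")
    out = np.empty_like(stack)
    for z, sl in enumerate(stack):
        lo, hi = sl.min(), sl.max()
        if hi == lo:
            logger.warning("slice %d is constant; set to zeros", z)
            out[z] = 0.0
            continue
        out[z] = _equalize_slice((sl - lo) / (hi - lo), bins)
    return out


def threshold_stack(
    stack: np.ndarray, fraction: float = DEFAULT_THRESHOLD_FRACTION
) -> np.ndarray:
    """Global binary mask: voxel ≥ fraction × whole-stack maximum."""
    stack = np.asarray(stack)
    peak = stack.max()
    if peak <= 0:
        return np.zeros(stack.shape, dtype=bool)
    return stack >= fraction * peak


def label_and_filter(
    mask: np.ndarray,
    min_voxels: int = DEFAULT_MIN_VOXELS,
    connectivity: int = 3,
) -> tuple[np.ndarray, int, dict]:
    """3D connected components with the minimum-volume filter.

    Components with strictly fewer than ``min_voxels`` voxels are removed
    (a component of exactly ``min_voxels`` survives); survivors are
    relabelled consecutively from 1.  ``connectivity`` 1/2/3 maps to
    6/18/26-neighbour adjacency.  Returns (labels, n_survivors, counts)
    where counts reconciles objects in = kept + removed.
    """
    structure = ndimage.generate_binary_structure(3, connectivity)
    labels, n = ndimage.label(np.asarray(mask, dtype=bool), structure=structure)
    if n == 0:
        return labels, 0, {"objects_in": 0, "kept": 0, "removed": 0}
    sizes = np.bincount(labels.ravel())
    keep = np.flatnonzero(sizes >= min_voxels)
    keep = keep[keep > 0]
    mapping = np.zeros(n + 1, dtype=labels.dtype)
    mapping[keep] = np.arange(1, keep.size + 1)
    return mapping[labels], int(keep.size), {
        "objects_in": int(n),
        "kept": int(keep.size),
        "removed": int(n - keep.size),
    }


def canal_centers_from_fits(fits: Sequence[EllipseFit]) -> dict[int, tuple[float, float]]:
    """Per-slice canal centre lookup from valid ellipse fits."""
    return {f.slice_index: (f.cx_um, f.cy_um) for f in fits if f.valid}


def locate_cells(
    labels: np.ndarray,
    voxel_size_um: tuple[float, float, float],
    canal_centers: Mapping[int, tuple[float, float]],
    z_window: int = 2,
) -> list[DetectedCell]:
    """Centroids, volumes and in-plane canal distances of labelled objects.

    The centroid is the unweighted voxel mean in μm (x = column·dx,
    y = row·dy, z = slice·dz).  The distance is the in-plane (x, y)
    Euclidean distance to the canal centre of the valid slice nearest the
    centroid's z, searched within ± ``z_window`` slices; cells without a
    reference are flagged ``no_reference`` with NaN distance.
    """
    dx, dy, dz = voxel_size_um
    if min(voxel_size_um) <= 0:
        raise ValueError("voxel dimensions must be positive")
    n_labels = int(labels.max())
    cells: list[DetectedCell] = []
    if n_labels == 0:
        return cells
    idx = np.arange(1, n_labels + 1)
    centroids = ndimage.center_of_mass(labels > 0, labels, idx)
    sizes = np.bincount(labels.ravel())
    for lab, (cz, cy_r, cx_c) in zip(idx, centroids):
        x_um = cx_c * dx
        y_um = cy_r * dy
        z_um = cz * dz
        z_slice = int(round(cz))
        vol = int(sizes[lab])
        cell = DetectedCell(
            label=int(lab),
            x_um=float(x_um),
            y_um=float(y_um),
            z_um=float(z_um),
            z_slice=z_slice,
            volume_voxels=vol,
            volume_um3=vol * dx * dy * dz,
        )
        candidates = [z for z in canal_centers if abs(z - z_slice) <= z_window]
        if not candidates:
            cell.no_reference = True
            logger.info("cell %d has no canal reference within ±%d slices", lab, z_window)
        else:
            z_ref = min(candidates, key=lambda z: (abs(z - z_slice), z))
            ccx, ccy = canal_centers[z_ref]
            cell.distance_um = math.hypot(x_um - ccx, y_um - ccy)
        cells.append(cell)
    return cells


@dataclass
class ZoneSummary:
    """Counts, zone percentages and distance ECDF for one group of cells.

    Percentages are over proximal + distal cells only; cells beyond the
    outer bound are counted separately as ``n_outside``.
    """

    group: str
    n_cells: int
    n_proximal: int
    n_distal: int
    n_outside: int
    n_no_reference: int
    percent_proximal: float  # NaN when no in-zone cells
    percent_distal: float
    cells_per_section_mean: float
    cells_per_section_sd: float
    distances_um: tuple[float, ...] = field(default_factory=tuple, repr=False)

    @property
    def ecdf(self) -> ECDF:
        return distance_ecdf_from_values(self.distances_um)


def classify_zones(
    cells: Sequence[DetectedCell],
    bounds_um: tuple[float, float] = DEFAULT_ZONE_BOUNDS_UM,
    section_ids: Sequence | None = None,
    group: str = "",
) -> ZoneSummary:
    """Assign proximal/distal/outside zones and summarize one cell group.

    proximal ⇔ d ≤ bounds[0]; distal ⇔ bounds[0] < d ≤ bounds[1];
    outside ⇔ d > bounds[1].  ``section_ids`` (aligned with ``cells``)
    defines the per-section grouping for the cells-per-section statistics;
    by default all cells form a single section.
    """
    low, high = bounds_um
    if not 0 < low < high:
        raise ValueError("zone bounds must satisfy 0 < low < high")
    n_prox = n_dist = n_out = n_noref = 0
    distances = []
    for cell in cells:
        if cell.no_reference or math.isnan(cell.distance_um):
            cell.zone = None
            n_noref += 1
            continue
        if cell.distance_um <= low:
            cell.zone = "proximal"
            n_prox += 1
        elif cell.distance_um <= high:
            cell.zone = "distal"
            n_dist += 1
        else:
            cell.zone = "outside"
            n_out += 1
        if cell.zone != "outside":
            distances.append(cell.distance_um)
    in_zone = n_prox + n_dist
    if section_ids is None:
        per_section = np.array([len(cells) - n_noref], dtype=float)
    else:
        counted = [
            sid for sid, cell in zip(section_ids, cells)
            if not (cell.no_reference or math.isnan(cell.distance_um))
        ]
        per_section = pd.Series(counted).value_counts().to_numpy(dtype=float)
        if per_section.size == 0:
            per_section = np.array([0.0])
    return ZoneSummary(
        group=group,
        n_cells=len(cells),
        n_proximal=n_prox,
        n_distal=n_dist,
        n_outside=n_out,
        n_no_reference=n_noref,
        percent_proximal=100.0 * n_prox / in_zone if in_zone else math.nan,
        percent_distal=100.0 * n_dist / in_zone if in_zone else math.nan,
        cells_per_section_mean=float(per_section.mean()),
        cells_per_section_sd=float(per_section.std(ddof=1)) if per_section.size > 1 else math.nan,
        distances_um=tuple(distances),
    )


def distance_ecdf_from_values(distances: Sequence[float]) -> ECDF:
    if len(distances) == 0:
        raise ValueError("ECDF requires at least one distance")
    return ECDF(np.asarray(distances, dtype=float), side="right")


def distance_ecdf(cells: Sequence[DetectedCell]) -> ECDF:
    """Right-continuous empirical CDF of cell-to-canal distances."""
    values = [c.distance_um for c in cells if not math.isnan(c.distance_um)]
    return distance_ecdf_from_values(values)


def detect_cells(
    stack: np.ndarray,
    voxel_size_um: tuple[float, float, float],
    canal_centers: Mapping[int, tuple[float, float]],
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
    min_voxels: int = DEFAULT_MIN_VOXELS,
    connectivity: int = 3,
    z_window: int = 2,
) -> tuple[list[DetectedCell], dict]:
    """Full detection chain on a cell-channel stack; returns cells + counts."""
    normalized = normalize_stack(stack)
    mask = threshold_stack(normalized, threshold_fraction)
    labels, n_kept, counts = label_and_filter(mask, min_voxels, connectivity)
    cells = locate_cells(labels, voxel_size_um, canal_centers, z_window)
    counts = dict(counts)
    counts["no_reference"] = sum(c.no_reference for c in cells)
    return cells, counts


def cells_to_frame(cells: Sequence[DetectedCell]) -> pd.DataFrame:
    """Cells as the canonical output table."""
    return pd.DataFrame(
        [
            {
                "label": c.label,
                "cx_um": c.x_um,
                "cy_um": c.y_um,
                "cz_um": c.z_um,
                "volume_voxels": c.volume_voxels,
                "volume_um3": c.volume_um3,
                "distance_um": c.distance_um,
                "zone": c.zone if c.zone is not None else "no_reference",
            }
            for c in cells
        ],
        columns=[
            "label", "cx_um", "cy_um", "cz_um",
            "volume_voxels", "volume_um3", "distance_um", "zone",
        ],
    )
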