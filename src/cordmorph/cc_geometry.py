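"""Central-canal segmentation and ellipse morphometry.

Per slice: Otsu threshold → 8-connected components → minimum-size filter →
keep the component whose centroid is nearest the frame centre → topological
closure check (the ependymal ring must enclose a lumen hole) → moments-based
ellipse fit of the hole-filled region.

Conventions
-----------
Coordinates: origin at the top-left pixel centre, x along columns, y along
rows, physical position = index × pixel size (μm).  Orientation is the
major-axis angle in degrees from the +x axis toward +y, period 180°.
Diameters are full axes obtained from the second central moments of the
filled region: d = 4·√λ for each covariance eigenvalue λ (exact for an
ideal filled ellipse).  Eccentricity = √(1 − (d_min/d_max)²); the analytic
ellipse area is π·d_min·d_max/4 and the pixel area is also reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import convex_hull_image

from .morphometry import cc_position as position_ratio

__all__ = [
    "position_ratio",
    "SegmentationResult",
    "EllipseFit",
    "MeanShape",
    "segment_canal",
    "validate_closure",
    "fit_ellipse",
    "analyze_slice",
    "analyze_stack",
    "mean_shape",
    "axial_circular_mean",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class SegmentationResult:
    """Selected canal component for one slice, or a named failure."""

    region: np.ndarray | None  # boolean mask of the selected component
    failure_reason: str | None = None

    @property
    def ok(self) -> bool:
        return self.region is not None


@dataclass
class EllipseFit:
    """Per-slice canal geometry; ``valid`` is False with ``failure_reason`` set otherwise."""

    slice_index: int
    valid: bool
    failure_reason: str | None = None
    cx_um: float = math.nan
    cy_um: float = math.nan
    d_min_um: float = math.nan
    d_max_um: float = math.nan
    orientation_deg: float = math.nan
    area_um2: float = math.nan  # analytic: pi * d_min * d_max / 4
    pixel_area_um2: float = math.nan  # filled-region pixel count * px^2
    eccentricity: float = math.nan


def segment_canal(
    img: np.ndarray, pixel_size_um: float, min_component_px: int = 200
) -> SegmentationResult:
    """Isolate the canal ring component in one slice.

    Otsu global threshold, 8-connected components, components smaller than
    ``min_component_px`` discarded, survivor with centroid nearest the frame
    centre selected.  Failures: ``"no-component"`` (constant image or no
    survivor), ``"truncated"`` (selected component touches the border).
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2D slice")
    if np.ptp(img) == 0:
        return SegmentationResult(None, "no-component")
    thresh = threshold_otsu(img)
    mask = img >= thresh
    labels, n = ndimage.label(mask, structure=_STRUCT8)
    if n == 0:
        return SegmentationResult(None, "no-component")
    sizes = np.bincount(labels.ravel())[1:]
    keep = np.flatnonzero(sizes >= min_component_px) + 1
    if keep.size == 0:
        return SegmentationResult(None, "no-component")
    centroids = ndimage.center_of_mass(mask, labels, keep)
    centre = (np.asarray(img.shape, dtype=float) - 1) / 2
    dists = [math.hypot(c[0] - centre[0], c[1] - centre[1]) for c in centroids]
    chosen = keep[int(np.argmin(dists))]
    region = labels == chosen
    if (
        region[0, :].any() or region[-1, :].any()
        or region[:, 0].any() or region[:, -1].any()
    ):
        return SegmentationResult(None, "truncated")
    return SegmentationResult(region)


def validate_closure(region: np.ndarray, solid_solidity: float = 0.9) -> str:
    """Classify the selected component as ``"closed"`` or ``"not_closed"``.

    Closed ⇔ the component encloses at least one background hole entirely
    inside the frame (the ring around the dark lumen).  Components without
    any hole are closed only if effectively solid (solidity ≥
    ``solid_solidity``), so a solid disc passes while a gapped arc does not.
    """
    region = np.asarray(region, dtype=bool)
    filled = ndimage.binary_fill_holes(region)
    if filled.sum() > region.sum():
        return "closed"
    hull = convex_hull_image(region)
    solidity = region.sum() / hull.sum() if hull.sum() else 0.0
    return "closed" if solidity >= solid_solidity else "not_closed"


def fit_ellipse(
    region: np.ndarray, pixel_size_um: float, slice_index: int = 0
) -> EllipseFit:
    """Moments-based ellipse fit of the lumen-filled region.

    The covariance of the filled pixel set (plus the px²/12 within-pixel
    term) gives eigenvalues λ with full diameters d = 4√λ; the orientation
    is the major eigenvector's angle.  Regions smaller than 5 px are
    degenerate and yield an invalid fit.
    """
    region = np.asarray(region, dtype=bool)
    filled = ndimage.binary_fill_holes(region)
    n_px = int(filled.sum())
    if n_px < 5:
        return EllipseFit(slice_index, False, "degenerate")
    rows, cols = np.nonzero(filled)
    x = cols * pixel_size_um
    y = rows * pixel_size_um
    cx = float(x.mean())
    cy = float(y.mean())
    dxv = x - cx
    dyv = y - cy
    cov = np.array(
        [
            [float((dxv * dxv).mean()), float((dxv * dyv).mean())],
            [float((dxv * dyv).mean()), float((dyv * dyv).mean())],
        ]
    )
    cov += np.eye(2) * pixel_size_um**2 / 12.0  # within-pixel variance
    evals, evecs = np.linalg.eigh(cov)  # ascending
    d_min = 4.0 * math.sqrt(max(evals[0], 0.0))
    d_max = 4.0 * math.sqrt(max(evals[1], 0.0))
    major = evecs[:, 1]
    orientation = math.degrees(math.atan2(major[1], major[0])) % 180.0
    ratio = d_min / d_max if d_max > 0 else 1.0
    return EllipseFit(
        slice_index=slice_index,
        valid=True,
        cx_um=cx,
        cy_um=cy,
        d_min_um=d_min,
        d_max_um=d_max,
        orientation_deg=orientation,
        area_um2=math.pi * d_min * d_max / 4.0,
        pixel_area_um2=n_px * pixel_size_um**2,
        eccentricity=math.sqrt(max(0.0, 1.0 - ratio**2)),
    )


def analyze_slice(
    img: np.ndarray,
    pixel_size_um: float,
    slice_index: int = 0,
    min_component_px: int = 200,
) -> EllipseFit:
    """Segment → closure check → fit for a single slice."""
    seg = segment_canal(img, pixel_size_um, min_component_px)
    if not seg.ok:
        return EllipseFit(slice_index, False, seg.failure_reason)
    if validate_closure(seg.region) != "closed":
        return EllipseFit(slice_index, False, "not_closed")
    return fit_ellipse(seg.region, pixel_size_um, slice_index)


def analyze_stack(
    stack: np.ndarray, pixel_size_um: float, min_component_px: int = 200
) -> tuple[list[EllipseFit], dict]:
    """Per-slice canal fits plus exclusion accounting.

    The accounting dict reconciles exactly: ``slices_in`` = ``valid`` +
    sum of the per-reason failure counts.
    """
    fits = [
        analyze_slice(sl, pixel_size_um, z, min_component_px)
        for z, sl in enumerate(np.asarray(stack))
    ]
    failures: dict[str, int] = {}
    for f in fits:
        if not f.valid:
            failures[f.failure_reason] = failures.get(f.failure_reason, 0) + 1
    accounting = {
        "slices_in": len(fits),
        "valid": sum(f.valid for f in fits),
        "failures": failures,
    }
    assert accounting["valid"] + sum(failures.values()) == accounting["slices_in"]
    return fits, accounting


# ---------------------------------------------------------------------------
# group mean shapes


def axial_circular_mean(angles_deg: Iterable[float]) -> tuple[float, float]:
    """Circular mean and sd of axial angles with 180° period.

    Angles are doubled onto the full circle, vector-averaged, and halved
    back; the sd is the circular standard deviation √(−2 ln R)/2 in degrees.
    """
    a = np.radians(np.asarray(list(angles_deg), dtype=float) * 2.0)
    if a.size == 0:
        raise ValueError("no angles")
    s = np.sin(a).mean()
    c = np.cos(a).mean()
    mean = math.degrees(math.atan2(s, c)) / 2.0 % 180.0
    r = min(1.0, math.hypot(s, c))
    sd = math.degrees(math.sqrt(max(0.0, -2.0 * math.log(r)))) / 2.0 if r > 0 else math.inf
    return mean, sd


@dataclass
class MeanShape:
    """Shape-only group average of canal ellipses (centres aligned to origin)."""

    group: str
    n: int
    mean_d_min_um: float
    sd_d_min_um: float
    mean_d_max_um: float
    sd_d_max_um: float
    mean_orientation_deg: float
    sd_orientation_deg: float

    @property
    def mean_eccentricity(self) -> float:
        ratio = self.mean_d_min_um / self.mean_d_max_um
        return math.sqrt(max(0.0, 1.0 - ratio**2))


def mean_shape(fits: Sequence[EllipseFit], group: str = "") -> MeanShape:
    """Average valid ellipse fits of one group into a mean shape."""
    valid = [f for f in fits if f.valid]
    if not valid:
        raise ValueError(f"no valid fits in group {group!r}")
    d_min = np.array([f.d_min_um for f in valid])
    d_max = np.array([f.d_max_um for f in valid])
    ori_mean, ori_sd = axial_circular_mean([f.orientation_deg for f in valid])
    return MeanShape(
        group=group,
        n=len(valid),
        mean_d_min_um=float(d_min.mean()),
        sd_d_min_um=float(d_min.std(ddof=1)) if len(valid) > 1 else 0.0,
        mean_d_max_um=float(d_max.mean()),
        sd_d_max_um=float(d_max.std(ddof=1)) if len(valid) > 1 else 0.0,
        mean_orientation_deg=ori_mean,
        sd_orientation_deg=ori_sd,
    )
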