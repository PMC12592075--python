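"""Synthetic confocal-like image stacks and cohort tables with known ground truth.

Three generators mirror the three kinds of data the analysis consumes:

* :func:`generate_canal_stack` — a DAPI-like stack in which each transverse
  slice shows the central canal as a bright elliptical ependymal ring with a
  dark CSF-filled lumen, on a noisy background.  The planted ellipse is the
  *outer* ring contour, i.e. exactly the contour the segmentation module
  fits after filling the lumen, so parameter recovery is well defined.
* :func:`generate_cell_stack` — a two-channel stack adding a tdTomato-like
  channel with compact bright cell blobs of exactly controlled voxel volume
  planted at controlled radial positions around the canal.
* :func:`generate_cohort` — a long-format landmark table with configurable
  additive age / sex / region effects and Gaussian section noise, nested in
  animals.

Every generator returns a :class:`GroundTruth` record of what was planted
and is bit-deterministic given (spec, seed).

Default imaging geometry follows the high-magnification acquisition the
pipeline is designed for: 0.31 × 0.31 μm pixels with 0.85 μm slice spacing.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .schema import (
    AGE_GROUPS,
    COHORT_COLUMNS,
    GENOTYPES,
    LANDMARKS,
    REGIONS,
    SEXES,
)

__all__ = [
    "GeometryError",
    "OverlapError",
    "CanalImageSpec",
    "CellSpec",
    "CellFieldSpec",
    "CohortSpec",
    "GroundTruth",
    "generate_canal_stack",
    "generate_cell_stack",
    "generate_cohort",
    "DEFAULT_BASELINE_MEANS",
    "DEFAULT_BASELINE_SDS",
]


class GeometryError(ValueError):
    """A planted object does not fit inside the requested frame."""


class OverlapError(ValueError):
    """Two planted objects overlap beyond the allowed fraction."""


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class GroundTruth:
    """Machine-readable record of everything a generator planted.

    ``ellipses`` holds one record per slice (outer canal contour in μm),
    ``cells`` one record per planted blob (centroid of the rendered voxel
    set, exact voxel volume, radial position), ``cohort_means`` the true
    per-group landmark means keyed by ``"age|sex|region"``.
    """

    ellipses: list[dict] = field(default_factory=list)
    cells: list[dict] = field(default_factory=list)
    cohort_means: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(**json.loads(text))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls.from_json(fh.read())


# ---------------------------------------------------------------------------
# canal stacks


@dataclass(frozen=True)
class CanalImageSpec:
    """Geometry and intensity model of a synthetic canal stack.

    The planted ellipse (``d_min_um``, ``d_max_um``, ``orientation_deg``)
    describes the outer contour of the bright ependymal ring; the ring
    extends inward by ``ring_thickness_um`` and the lumen inside is dark.
    Orientation is the major-axis angle in degrees, measured from the image
    x axis (columns) toward the y axis (rows), period 180°.
    """

    image_shape: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.31
    n_slices: int = 8
    slice_spacing_um: float = 0.85
    ellipse_center_um: tuple[float, float] | None = None  # default: frame centre
    d_min_um: float = 17.8
    d_max_um: float = 42.5
    orientation_deg: float = 0.0
    ring_thickness_um: float = 3.0
    foreground_level: float = 0.8
    background_level: float = 0.15
    noise_sd: float = 0.02
    seed: int = 0

    def center_um(self) -> tuple[float, float]:
        if self.ellipse_center_um is not None:
            return self.ellipse_center_um
        rows, cols = self.image_shape
        return ((cols - 1) / 2 * self.pixel_size_um, (rows - 1) / 2 * self.pixel_size_um)

    def validate(self) -> None:
        if self.d_min_um <= 0 or self.d_max_um <= 0:
            raise GeometryError("ellipse diameters must be positive")
        if self.d_min_um > self.d_max_um:
            raise GeometryError("d_min_um must not exceed d_max_um")
        if not 0 < self.ring_thickness_um < self.d_min_um / 2:
            raise GeometryError("ring_thickness_um must lie in (0, d_min_um/2)")
        if self.foreground_level <= self.background_level:
            raise GeometryError("foreground_level must exceed background_level")
        if self.pixel_size_um <= 0 or self.n_slices < 1:
            raise GeometryError("invalid sampling geometry")
        # bounding half-extents of the rotated outer ellipse
        a = self.d_max_um / 2
        b = self.d_min_um / 2
        th = math.radians(self.orientation_deg)
        hx = math.hypot(a * math.cos(th), b * math.sin(th))
        hy = math.hypot(a * math.sin(th), b * math.cos(th))
        margin = 2 * self.pixel_size_um
        cx, cy = self.center_um()
        rows, cols = self.image_shape
        if (
            cx - hx < margin
            or cy - hy < margin
            or cx + hx > (cols - 1) * self.pixel_size_um - margin
            or cy + hy > (rows - 1) * self.pixel_size_um - margin
        ):
            raise GeometryError(
                f"ellipse (half-extents {hx:.1f} x {hy:.1f} um) does not fit the "
                f"{rows}x{cols} frame with a 2 px margin"
            )


def _ellipse_mask(
    shape: tuple[int, int],
    pixel_size: float,
    center: tuple[float, float],
    d_min: float,
    d_max: float,
    orientation_deg: float,
) -> np.ndarray:
    """Boolean mask of pixel centres inside the given ellipse (μm frame)."""
    rows, cols = shape
    y = np.arange(rows)[:, None] * pixel_size - center[1]
    x = np.arange(cols)[None, :] * pixel_size - center[0]
    th = math.radians(orientation_deg)
    u = x * math.cos(th) + y * math.sin(th)
    v = -x * math.sin(th) + y * math.cos(th)
    a = d_max / 2
    b = d_min / 2
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _render_canal_slice(spec: CanalImageSpec, rng: np.random.Generator) -> np.ndarray:
    cx, cy = spec.center_um()
    outer = _ellipse_mask(
        spec.image_shape, spec.pixel_size_um, (cx, cy),
        spec.d_min_um, spec.d_max_um, spec.orientation_deg,
    )
    inner = _ellipse_mask(
        spec.image_shape, spec.pixel_size_um, (cx, cy),
        spec.d_min_um - 2 * spec.ring_thickness_um,
        spec.d_max_um - 2 * spec.ring_thickness_um,
        spec.orientation_deg,
    )
    img = np.full(spec.image_shape, spec.background_level, dtype=np.float64)
    img[outer & ~inner] = spec.foreground_level
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=spec.image_shape)
    return np.clip(img, 0.0, 1.0).astype(np.float32)


def generate_canal_stack(spec: CanalImageSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render an ``(n_slices, rows, cols)`` float32 stack plus ground truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    stack = np.stack([_render_canal_slice(spec, rng) for _ in range(spec.n_slices)])
    cx, cy = spec.center_um()
    ratio = spec.d_min_um / spec.d_max_um
    truth = GroundTruth(
        ellipses=[
            {
                "slice": z,
                "cx_um": cx,
                "cy_um": cy,
                "d_min_um": spec.d_min_um,
                "d_max_um": spec.d_max_um,
                "orientation_deg": spec.orientation_deg % 180.0,
                "area_um2": math.pi * spec.d_min_um * spec.d_max_um / 4,
                "eccentricity": math.sqrt(max(0.0, 1.0 - ratio**2)),
            }
            for z in range(spec.n_slices)
        ]
    )
    return stack, truth


# ---------------------------------------------------------------------------
# cell stacks


@dataclass(frozen=True)
class CellSpec:
    """One planted cell: polar position around the canal centre and size.

    ``volume_voxels`` is exact: the rendered blob is the superlevel set of
    an anisotropic Gaussian truncated to precisely that many voxels, all at
    ``peak_intensity``, so the detection chain's above-threshold voxel count
    equals the planted volume.
    """

    radial_distance_um: float
    polar_angle_deg: float
    z_slice: int
    volume_voxels: int
    peak_intensity: float = 0.9


@dataclass(frozen=True)
class CellFieldSpec:
    """Two-channel field: canal channel plus tdTomato-like cell channel."""

    canal: CanalImageSpec
    cells: tuple[CellSpec, ...] = ()
    seed: int = 0
    max_overlap_fraction: float = 0.0
    cell_background_level: float = 0.1
    cell_noise_sd: float = 0.0
    zone_bounds_um: tuple[float, float] = (100.0, 230.0)

    def validate(self) -> None:
        self.canal.validate()
        for c in self.cells:
            if c.volume_voxels < 1:
                raise ValueError("volume_voxels must be >= 1")
            if c.radial_distance_um < 0:
                raise ValueError("radial_distance_um must be >= 0")
            if not 0 <= c.z_slice < self.canal.n_slices:
                raise GeometryError("z_slice outside stack")
            if c.peak_intensity <= self.cell_background_level:
                raise ValueError("peak_intensity must exceed cell background")


def _blob_voxels(
    center_um: tuple[float, float, float],
    volume_voxels: int,
    voxel: tuple[float, float, float],
    grid_shape: tuple[int, int, int],
) -> np.ndarray:
    """Indices (N, 3) as (z, y, x) of the blob's exact voxel set.

    The set comprises the ``volume_voxels`` voxels whose centres are closest
    to ``center_um`` in physical distance (an ellipsoid in index space,
    a ball in μm), with deterministic raster-order tie-breaking.
    """
    dx, dy, dz = voxel
    n_z, n_y, n_x = grid_shape
    cx, cy, cz = center_um
    # physical radius of a ball holding the requested volume, with margin
    r_um = (3 * volume_voxels * dx * dy * dz / (4 * math.pi)) ** (1 / 3)
    r_um *= 1.8
    z0, z1 = int(math.floor((cz - r_um) / dz)), int(math.ceil((cz + r_um) / dz))
    y0, y1 = int(math.floor((cy - r_um) / dy)), int(math.ceil((cy + r_um) / dy))
    x0, x1 = int(math.floor((cx - r_um) / dx)), int(math.ceil((cx + r_um) / dx))
    zz = np.arange(z0, z1 + 1)
    yy = np.arange(y0, y1 + 1)
    xx = np.arange(x0, x1 + 1)
    d2 = (
        ((zz * dz - cz) ** 2)[:, None, None]
        + ((yy * dy - cy) ** 2)[None, :, None]
        + ((xx * dx - cx) ** 2)[None, None, :]
    )
    flat = d2.ravel()
    if volume_voxels > flat.size:
        raise GeometryError("blob bounding box smaller than requested volume")
    order = np.argsort(flat, kind="stable")[:volume_voxels]
    kz, ky, kx = np.unravel_index(order, d2.shape)
    idx = np.stack([kz + z0, ky + y0, kx + x0], axis=1)
    if (
        idx[:, 0].min() < 0 or idx[:, 0].max() >= n_z
        or idx[:, 1].min() < 0 or idx[:, 1].max() >= n_y
        or idx[:, 2].min() < 0 or idx[:, 2].max() >= n_x
    ):
        raise GeometryError(
            f"cell of {volume_voxels} voxels at ({cx:.1f}, {cy:.1f}) um, slice "
            f"{cz / dz:.0f} extends outside the stack"
        )
    return idx


def generate_cell_stack(spec: CellFieldSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a ``(2, n_slices, rows, cols)`` stack: canal channel + cells.

    Channel 0 is the canal channel (as :func:`generate_canal_stack`);
    channel 1 carries the planted blobs on its own background.  Cells must
    not overlap each other beyond ``max_overlap_fraction`` of the smaller
    cell, nor the canal ring footprint.
    """
    spec.validate()
    canal = spec.canal
    canal_stack, truth = generate_canal_stack(canal)
    rows, cols = canal.image_shape
    grid_shape = (canal.n_slices, rows, cols)
    dx = dy = canal.pixel_size_um
    dz = canal.slice_spacing_um
    rng = np.random.default_rng(spec.seed)

    ch2 = np.full(grid_shape, spec.cell_background_level, dtype=np.float64)
    if spec.cell_noise_sd > 0:
        ch2 += rng.normal(0.0, spec.cell_noise_sd, size=grid_shape)

    ccx, ccy = canal.center_um()
    occupied: dict[int, int] = {}
    low, high = spec.zone_bounds_um
    for i, cell in enumerate(spec.cells):
        th = math.radians(cell.polar_angle_deg)
        cx = ccx + cell.radial_distance_um * math.cos(th)
        cy = ccy + cell.radial_distance_um * math.sin(th)
        cz = cell.z_slice * dz
        idx = _blob_voxels((cx, cy, cz), cell.volume_voxels, (dx, dy, dz), grid_shape)
        # reject blobs whose footprint intrudes into the canal ring
        xu = idx[:, 2] * dx
        yu = idx[:, 1] * dy
        thc = math.radians(canal.orientation_deg)
        u = (xu - ccx) * math.cos(thc) + (yu - ccy) * math.sin(thc)
        v = -(xu - ccx) * math.sin(thc) + (yu - ccy) * math.cos(thc)
        if np.any((u / (canal.d_max_um / 2)) ** 2 + (v / (canal.d_min_um / 2)) ** 2 <= 1.0):
            raise GeometryError(f"cell {i} overlaps the canal ring footprint")
        lin = np.ravel_multi_index((idx[:, 0], idx[:, 1], idx[:, 2]), grid_shape)
        shared = sum(1 for k in lin if int(k) in occupied)
        if shared:
            for j in set(occupied[int(k)] for k in lin if int(k) in occupied):
                frac = shared / min(cell.volume_voxels, spec.cells[j].volume_voxels)
                if frac > spec.max_overlap_fraction:
                    raise OverlapError(
                        f"cells {j} and {i} share {shared} voxels "
                        f"({frac:.1%} > allowed {spec.max_overlap_fraction:.1%})"
                    )
        for k in lin:
            occupied.setdefault(int(k), i)
        ch2[idx[:, 0], idx[:, 1], idx[:, 2]] = cell.peak_intensity
        centroid_x = float(xu.mean())
        centroid_y = float(yu.mean())
        centroid_z = float((idx[:, 0] * dz).mean())
        dist = math.hypot(centroid_x - ccx, centroid_y - ccy)
        if dist <= low:
            zone = "proximal"
        elif dist <= high:
            zone = "distal"
        else:
            zone = "outside"
        truth.cells.append(
            {
                "cell": i,
                "x_um": centroid_x,
                "y_um": centroid_y,
                "z_um": centroid_z,
                "z_slice": cell.z_slice,
                "volume_voxels": int(cell.volume_voxels),
                "radial_distance_um": dist,
                "polar_angle_deg": cell.polar_angle_deg % 360.0,
                "zone": zone,
            }
        )
    ch2 = np.clip(ch2, 0.0, 1.0).astype(np.float32)
    return np.stack([canal_stack, ch2]), truth


def concentric_cell_layout(
    n_cells: int,
    volume_voxels: int,
    n_distractors: int = 0,
    distractor_volume_voxels: int = 500,
    r_start_um: float = 28.0,
    spacing_um: float = 13.0,
    z_slice: int = 10,
    peak_intensity: float = 0.9,
) -> tuple[CellSpec, ...]:
    """Deterministic non-overlapping cell placement on concentric rings.

    Positions are laid out ring by ring with at least ``spacing_um``
    in-plane separation; the first ``n_cells`` get ``volume_voxels``, the
    next ``n_distractors`` get ``distractor_volume_voxels``.  All share one
    z slice and peak intensity, so the whole field survives per-slice
    equalization together.
    """
    total = n_cells + n_distractors
    positions: list[tuple[float, float]] = []
    r = r_start_um
    while len(positions) < total:
        n_on_ring = max(1, int(2 * math.pi * r / spacing_um))
        offset = 360.0 / n_on_ring / 2 * (len(positions) % 2)
        for k in range(n_on_ring):
            if len(positions) >= total:
                break
            positions.append((r, offset + k * 360.0 / n_on_ring))
        r += spacing_um
    return tuple(
        CellSpec(
            radial_distance_um=pr,
            polar_angle_deg=pa,
            z_slice=z_slice,
            volume_voxels=volume_voxels if i < n_cells else distractor_volume_voxels,
            peak_intensity=peak_intensity,
        )
        for i, (pr, pa) in enumerate(positions)
    )


# ---------------------------------------------------------------------------
# cohort tables

#: Default per-landmark baseline means and sds (μm): the young-adult (8wo)
#: male operating point of the cohort the generator emulates.
DEFAULT_BASELINE_MEANS: Mapping[str, float] = {
    "AP": 765.0, "T": 1014.0, "VWC": 358.0, "DMS": 362.0, "LWM": 507.0,
    "MWM": 507.0, "AW": 787.0, "PW": 618.0, "VGC": 340.0, "DGC": 340.0,
    "LVH": 94.0, "RVH": 73.0, "LDH": 415.0, "RDH": 428.0,
}
DEFAULT_BASELINE_SDS: Mapping[str, float] = {
    "AP": 94.0, "T": 188.0, "VWC": 49.0, "DMS": 54.0, "LWM": 95.0,
    "MWM": 95.0, "AW": 137.0, "PW": 211.0, "VGC": 76.0, "DGC": 77.0,
    "LVH": 39.0, "RVH": 28.0, "LDH": 63.0, "RDH": 67.0,
}


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic landmark cohort.

    Effects are additive shifts in μm: ``age_effects`` applies to the second
    age group (8wo), ``sex_effects`` to males, ``region_effects`` maps
    region → landmark → shift.  Section noise is Gaussian with the baseline
    sds scaled by ``noise_scale``, truncated at zero.  ``sections_per_segment``
    defaults to the 22 sections per spinal segment of the emulated design.
    """

    n_animals_per_cell: int = 2
    sections_per_segment: int = 22
    baseline_means: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BASELINE_MEANS))
    baseline_sds: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BASELINE_SDS))
    age_effects: Mapping[str, float] = field(default_factory=dict)
    sex_effects: Mapping[str, float] = field(default_factory=dict)
    region_effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    ages: Sequence[str] = AGE_GROUPS
    sexes: Sequence[str] = SEXES
    regions: Sequence[str] = REGIONS
    n_replicates: int = 1
    replicate_cov_percent: float = 0.0
    noise_scale: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        for lm in LANDMARKS:
            if self.baseline_means.get(lm, 0.0) <= 0:
                raise ValueError(f"baseline mean for {lm} must be > 0")
            if self.baseline_sds.get(lm, -1.0) < 0:
                raise ValueError(f"baseline sd for {lm} must be >= 0")
        if self.n_animals_per_cell < 1 or self.sections_per_segment < 1 or self.n_replicates < 1:
            raise ValueError("counts must be >= 1")
        for a in self.ages:
            if a not in AGE_GROUPS:
                raise ValueError(f"unknown age group {a!r}")
        for s in self.sexes:
            if s not in SEXES:
                raise ValueError(f"unknown sex {s!r}")
        for r in self.regions:
            if r not in REGIONS:
                raise ValueError(f"unknown region {r!r}")

    def true_mean(self, landmark: str, age: str, sex: str, region: str) -> float:
        m = float(self.baseline_means[landmark])
        if age == "8wo":
            m += float(self.age_effects.get(landmark, 0.0))
        if sex == "M":
            m += float(self.sex_effects.get(landmark, 0.0))
        m += float(self.region_effects.get(region, {}).get(landmark, 0.0))
        return m


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, GroundTruth]:
    """Long-format cohort table (one row per section × replicate) + truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows: list[dict] = []
    truth = GroundTruth()
    animal_counter = 0
    for age in spec.ages:
        for sex in spec.sexes:
            for region in spec.regions:
                key = f"{age}|{sex}|{region}"
                truth.cohort_means[key] = {
                    lm: spec.true_mean(lm, age, sex, region) for lm in LANDMARKS
                }
            for a in range(spec.n_animals_per_cell):
                animal_counter += 1
                animal_id = f"M{animal_counter:03d}"
                genotype = GENOTYPES[a % len(GENOTYPES)]
                for region in spec.regions:
                    for s in range(spec.sections_per_segment):
                        section_id = f"{animal_id}_{region}_{s + 1:03d}"
                        base = {
                            lm: max(
                                0.0,
                                spec.true_mean(lm, age, sex, region)
                                + spec.noise_scale
                                * float(spec.baseline_sds[lm])
                                * rng.standard_normal(),
                            )
                            for lm in LANDMARKS
                        }
                        for rep in range(1, spec.n_replicates + 1):
                            row = {
                                "animal_id": animal_id,
                                "section_id": section_id,
                                "replicate": rep,
                                "age_group": age,
                                "sex": sex,
                                "genotype": genotype,
                                "region": region,
                            }
                            if spec.n_replicates > 1 and spec.replicate_cov_percent > 0:
                                jitter = spec.replicate_cov_percent / 100.0
                                row.update(
                                    {
                                        lm: max(0.0, v * (1 + jitter * rng.standard_normal()))
                                        for lm, v in base.items()
                                    }
                                )
                            else:
                                row.update(base)
                            rows.append(row)
    table = pd.DataFrame(rows, columns=list(COHORT_COLUMNS))
    return table, truth
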