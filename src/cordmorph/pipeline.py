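"""End-to-end pipeline driver: simulate → segment → detect → morphometry → stats.

``run_pipeline`` executes every stage under one :class:`~cordmorph.config.RunConfig`,
writes the canonical CSV/JSON artifacts into the output directory and
returns the run log.  Outputs are bit-deterministic given (inputs, config,
seed); the run log carries the exclusion accounting of every stage plus
the config hash (its wall-clock timestamp is the only non-deterministic
field).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .cc_geometry import analyze_stack, mean_shape
from .cell_mapping import (
    canal_centers_from_fits,
    cells_to_frame,
    classify_zones,
    detect_cells,
)
from .config import RunConfig
from .group_stats import compare_two_groups, kendall_matrix, region_cascade
from .io import write_stack, write_table
from .morphometry import derive_measures_table, summarize
from .schema import LANDMARKS
from .synthetic import (
    CanalImageSpec,
    CellFieldSpec,
    CellSpec,
    CohortSpec,
    generate_cell_stack,
    generate_cohort,
)

__all__ = ["run_pipeline", "demo_cell_field_spec", "demo_cohort_spec"]

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


def demo_cell_field_spec(config: RunConfig) -> CellFieldSpec:
    """Deterministic demo field: a canal ring with cells on a ring around it.

    Cells are placed on an annulus clear of both the canal footprint and
    the frame border, at evenly spread polar angles, centred in z.
    """
    canal = CanalImageSpec(
        image_shape=config.image_shape,
        pixel_size_um=config.pixel_size_um,
        n_slices=config.n_slices,
        slice_spacing_um=config.slice_spacing_um,
        seed=config.seed,
    )
    half_extent = (min(config.image_shape) - 1) / 2 * config.pixel_size_um
    blob_r = (
        3 * config.cell_volume_voxels
        * config.pixel_size_um**2 * config.slice_spacing_um
        / (4 * math.pi)
    ) ** (1 / 3)
    r_lo = canal.d_max_um / 2 + blob_r + 2.0
    r_hi = half_extent - blob_r - 3 * config.pixel_size_um
    if r_lo >= r_hi:
        raise StageError("simulate: frame too small for the demo cell annulus")
    cells = tuple(
        CellSpec(
            radial_distance_um=r_lo + (r_hi - r_lo) * (0.5 if config.n_cells == 1 else i / (config.n_cells - 1)),
            polar_angle_deg=i * 360.0 / max(config.n_cells, 1),
            z_slice=config.n_slices // 2,
            volume_voxels=config.cell_volume_voxels,
        )
        for i in range(config.n_cells)
    )
    return CellFieldSpec(canal=canal, cells=cells, seed=config.seed)


def demo_cohort_spec(config: RunConfig) -> CohortSpec:
    # cervical/lumbar enlargements give the region screen something to find
    return CohortSpec(
        n_animals_per_cell=config.cohort_animals_per_cell,
        sections_per_segment=config.cohort_sections_per_segment,
        age_effects={"AP": config.cohort_age_effect_ap_um},
        region_effects={
            "cervical": {"T": 120.0, "AW": 80.0},
            "lumbar": {"T": 60.0, "AW": 110.0},
        },
        seed=config.seed,
    )


def _fits_frame(fits) -> pd.DataFrame:
    rows = []
    for f in fits:
        d = dataclasses.asdict(f)
        d["slice"] = d.pop("slice_index")
        d["failure_reason"] = d["failure_reason"] or ""
        rows.append(d)
    return pd.DataFrame(rows)[
        [
            "slice", "valid", "failure_reason", "cx_um", "cy_um",
            "d_min_um", "d_max_um", "orientation_deg", "area_um2",
            "eccentricity", "pixel_area_um2",
        ]
    ]


def run_pipeline(config: RunConfig, cohort: pd.DataFrame | None = None) -> dict:
    """Run all stages; returns the run log (also written to run_log.json)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "version": __version__,
        "config_hash": config.config_hash,
        "stages": {},
    }

    # --- simulate -----------------------------------------------------
    if config.simulate:
        try:
            field_spec = demo_cell_field_spec(config)
            stack, truth = generate_cell_stack(field_spec)
            write_stack(stack, out / "stacks.tif")
            truth.save(out / "stacks.truth.json")
        except Exception as exc:  # noqa: BLE001 - stage boundary
            raise StageError(f"simulate: {exc}") from exc
        if cohort is None:
            cohort_spec = demo_cohort_spec(config)
            cohort, cohort_truth = generate_cohort(cohort_spec)
            cohort_truth.save(out / "cohort.truth.json")
        write_table(cohort, out / "cohort.csv")
        log["stages"]["simulate"] = {
            "n_cells_planted": len(truth.cells),
            "cohort_rows": int(len(cohort)),
        }
    else:
        if cohort is None:
            raise StageError("simulate disabled and no cohort table provided")
        stack = None

    # --- segment central canal ---------------------------------------
    if stack is not None:
        try:
            fits, accounting = analyze_stack(
                stack[0], config.pixel_size_um, config.min_component_px
            )
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"segment-cc: {exc}") from exc
        write_table(_fits_frame(fits), out / "cc_fits.csv")
        valid_fits = [f for f in fits if f.valid]
        if valid_fits:
            shape = mean_shape(valid_fits, group="all")
            (out / "mean_shape.json").write_text(
                json.dumps(dataclasses.asdict(shape), indent=1, sort_keys=True)
            )
        log["stages"]["segment_cc"] = accounting

        # --- detect cells ---------------------------------------------
        try:
            centers = canal_centers_from_fits(valid_fits)
            voxel = (config.pixel_size_um, config.pixel_size_um, config.slice_spacing_um)
            cells, counts = detect_cells(
                stack[1],
                voxel,
                centers,
                threshold_fraction=config.threshold_fraction,
                min_voxels=config.min_voxels,
                connectivity=config.connectivity,
                z_window=config.z_window,
            )
            summary = classify_zones(cells, config.zone_bounds_um, group="all")
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"detect-cells: {exc}") from exc
        write_table(cells_to_frame(cells), out / "cells.csv")
        zs = {
            k: v for k, v in dataclasses.asdict(summary).items() if k != "distances_um"
        }
        write_table(pd.DataFrame([zs]), out / "zone_summary.csv")
        log["stages"]["detect_cells"] = counts

    # --- morphometry ---------------------------------------------------
    try:
        derived = derive_measures_table(cohort, config.commissure_definition)
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"morphometry: {exc}") from exc
    write_table(derived, out / "derived.csv")
    summaries = []
    for (age, sex), g in cohort.groupby(["age_group", "sex"], observed=True):
        for lm in LANDMARKS:
            s = summarize(g[lm])
            summaries.append(
                {
                    "age_group": age,
                    "sex": sex,
                    "length": lm,
                    "n": s.n,
                    "mean": s.mean,
                    "sd": s.sd,
                    "min": s.min,
                    "max": s.max,
                    "formatted": s.formatted,
                }
            )
    write_table(pd.DataFrame(summaries), out / "group_summary.csv")
    log["stages"]["morphometry"] = {"rows": int(len(derived))}

    # --- statistics ----------------------------------------------------
    try:
        tests = []
        for lm in LANDMARKS:
            by_sex = compare_two_groups(
                cohort.loc[cohort["sex"] == "F", lm],
                cohort.loc[cohort["sex"] == "M", lm],
                alpha=config.alpha,
                equal_var=config.equal_var_ttest,
            )
            by_age = compare_two_groups(
                cohort.loc[cohort["age_group"] == "3wo", lm],
                cohort.loc[cohort["age_group"] == "8wo", lm],
                alpha=config.alpha,
                equal_var=config.equal_var_ttest,
            )
            tests.append(
                {
                    "length": lm,
                    "sex_test": by_sex.test_name,
                    "sex_p": by_sex.p_value,
                    "sex_stars": by_sex.stars,
                    "age_test": by_age.test_name,
                    "age_p": by_age.p_value,
                    "age_stars": by_age.stars,
                }
            )
        write_table(pd.DataFrame(tests), out / "age_sex_tests.csv")
        cascade = region_cascade(cohort, LANDMARKS, "region", config.alpha)
        write_table(cascade, out / "region_effects.csv")
        corr = kendall_matrix(cohort, LANDMARKS)
        corr.to_frame().to_csv(out / "kendall.csv")
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stats: {exc}") from exc
    log["stages"]["stats"] = {
        "n_two_group_tests": len(tests),
        "n_manova_responses": int(cascade["entered_manova"].sum()),
    }

    # --- report --------------------------------------------------------
    log["timestamp"] = datetime.now(timezone.utc).isoformat()
    (out / "run_log.json").write_text(json.dumps(log, indent=1, sort_keys=True))
    return log
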