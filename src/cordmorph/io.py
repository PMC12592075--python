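"""Readers and writers for the pipeline's external formats.

Image stacks travel as multi-page TIFF (grayscale, float32; two-channel
stacks as a (2, z, y, x) series), cohort tables as CSV with the canonical
column order, ground truth as a ``.truth.json`` sidecar.  Reads validate
the schema (required columns, closed vocabularies, non-negative lengths)
and round-trip losslessly; unknown extra columns are preserved.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .schema import (
    AGE_GROUPS,
    COHORT_COLUMNS,
    GENOTYPES,
    LANDMARKS,
    MAX_LENGTH_UM,
    REGIONS,
    SEXES,
)

__all__ = [
    "SchemaError",
    "read_stack",
    "write_stack",
    "read_landmarks",
    "write_table",
    "truth_sidecar_path",
]


class SchemaError(ValueError):
    """An input file does not conform to the documented schema."""


def write_stack(stack: np.ndarray, path) -> None:
    """Write a (z, y, x) or (c, z, y, x) float stack as multi-page TIFF."""
    arr = np.asarray(stack, dtype=np.float32)
    if arr.ndim not in (3, 4):
        raise ValueError("expected a (z, y, x) or (c, z, y, x) stack")
    tifffile.imwrite(path, arr, photometric="minisblack")


def read_stack(path) -> np.ndarray:
    """Read a multi-page TIFF written by :func:`write_stack`."""
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    return np.asarray(arr)


def truth_sidecar_path(stack_path) -> Path:
    """Ground-truth sidecar path: same basename with ``.truth.json``."""
    p = Path(stack_path)
    return p.with_suffix("").with_suffix(".truth.json") if p.suffix else p.with_suffix(".truth.json")


_ENUMS = {"age_group": AGE_GROUPS, "sex": SEXES, "genotype": GENOTYPES, "region": REGIONS}


def validate_landmarks(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a cohort table's schema in place and return it."""
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    for col, vocab in _ENUMS.items():
        bad = set(table[col].astype(str)) - set(vocab)
        if bad:
            raise SchemaError(f"column {col!r} contains unknown value(s): {sorted(bad)}")
    for lm in LANDMARKS:
        vals = pd.to_numeric(table[lm], errors="coerce")
        if vals.isna().any():
            row = int(vals.index[vals.isna()][0])
            raise SchemaError(f"non-numeric {lm} at row {row}")
        if (vals < 0).any():
            row = int(vals.index[vals < 0][0])
            raise SchemaError(f"negative length {lm} at row {row}")
        if (vals > MAX_LENGTH_UM).any():
            row = int(vals.index[vals > MAX_LENGTH_UM][0])
            raise SchemaError(
                f"{lm} at row {row} exceeds the {MAX_LENGTH_UM:.0f} um sanity bound"
            )
        table[lm] = vals.astype(float)
    return table


def read_landmarks(path) -> pd.DataFrame:
    """Read and validate a cohort landmark CSV (lengths in μm)."""
    table = pd.read_csv(path)
    return validate_landmarks(table)


def write_table(table: pd.DataFrame, path, columns: Sequence[str] | None = None) -> None:
    """Write a table as CSV without the index, optionally ordering columns."""
    if columns is not None:
        ordered = [c for c in columns if c in table.columns]
        extra = [c for c in table.columns if c not in ordered]
        table = table[ordered + extra]
    table.to_csv(path, index=False)
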