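"""Landmark morphometry: derived ratios, repeatability COV, group summaries.

Works on the 14 per-section landmark lengths (μm).  Derived quantities are
the diameter and horn ratios, the commissure sum VGC+DGC, a pluggable
commissure-size field and the normalized dorso-ventral canal position
VWC/(VWC+DMS).  Ratios with a zero denominator are flagged as undefined
(NaN plus the offending field name), never silently dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .schema import LANDMARKS

__all__ = [
    "DerivedMeasures",
    "CovReport",
    "GroupSummary",
    "COMMISSURE_DEFINITIONS",
    "derive_measures",
    "derive_measures_table",
    "repeatability_cov",
    "summarize",
    "cc_position",
]

#: Pluggable definitions of the commissure-size field.  The default
#: ``half_sum`` = (VWC+DMS)/2 is a package convention, not an established
#: formula for this quantity.
COMMISSURE_DEFINITIONS: Mapping[str, Callable[[Mapping[str, float]], float]] = {
    "half_sum": lambda lm: (lm["VWC"] + lm["DMS"]) / 2.0,
    "sum": lambda lm: lm["VWC"] + lm["DMS"],
    "vwc": lambda lm: lm["VWC"],
}


@dataclass
class DerivedMeasures:
    """Derived per-section quantities; ``undefined`` names NaN-valued fields."""

    ap_t_ratio: float
    aw_pw_ratio: float
    rvh_rdh_ratio: float
    lvh_ldh_ratio: float
    vgc_dgc_sum: float
    commissure_size: float
    cc_position: float
    undefined: tuple[str, ...] = ()


def _ratio(num: float, den: float, name: str, undefined: list[str]) -> float:
    if den == 0:
        undefined.append(name)
        return math.nan
    return num / den


def cc_position(vwc: float, dms: float) -> float:
    """Normalized canal position VWC/(VWC+DMS) in [0, 1]; larger = more dorsal.

    Returns NaN when VWC + DMS = 0.
    """
    if vwc < 0 or dms < 0:
        raise ValueError("lengths must be non-negative")
    total = vwc + dms
    return math.nan if total == 0 else vwc / total


def derive_measures(
    lm: Mapping[str, float], commissure_definition: str = "half_sum"
) -> DerivedMeasures:
    """Compute all derived measures for one section's landmark lengths."""
    for key in LANDMARKS:
        if lm[key] < 0:
            raise ValueError(f"negative length for {key}")
    undefined: list[str] = []
    commissure = COMMISSURE_DEFINITIONS[commissure_definition]
    pos = cc_position(lm["VWC"], lm["DMS"])
    if math.isnan(pos):
        undefined.append("cc_position")
    return DerivedMeasures(
        ap_t_ratio=_ratio(lm["AP"], lm["T"], "ap_t_ratio", undefined),
        aw_pw_ratio=_ratio(lm["AW"], lm["PW"], "aw_pw_ratio", undefined),
        rvh_rdh_ratio=_ratio(lm["RVH"], lm["RDH"], "rvh_rdh_ratio", undefined),
        lvh_ldh_ratio=_ratio(lm["LVH"], lm["LDH"], "lvh_ldh_ratio", undefined),
        vgc_dgc_sum=lm["VGC"] + lm["DGC"],
        commissure_size=commissure(lm),
        cc_position=pos,
        undefined=tuple(undefined),
    )


_DERIVED_FIELDS = (
    "ap_t_ratio", "aw_pw_ratio", "rvh_rdh_ratio", "lvh_ldh_ratio",
    "vgc_dgc_sum", "commissure_size", "cc_position",
)


def derive_measures_table(
    table: pd.DataFrame, commissure_definition: str = "half_sum"
) -> pd.DataFrame:
    """Append the derived-measure columns to a cohort table (copy)."""
    out = table.copy()
    derived = [
        derive_measures({k: row[k] for k in LANDMARKS}, commissure_definition)
        for _, row in table.iterrows()
    ]
    for f in _DERIVED_FIELDS:
        out[f] = [getattr(d, f) for d in derived]
    return out


# ---------------------------------------------------------------------------
# repeatability


@dataclass
class CovReport:
    """Per-landmark repeatability of replicate placements.

    ``per_length`` has one row per landmark with the mean and sd of the
    per-section COV (%) and the pass flag (mean COV < threshold); sections
    whose replicate mean is zero yield an undefined (NaN) COV, counted in
    ``n_undefined``.
    """

    per_length: pd.DataFrame
    threshold_percent: float = 5.0
    n_sections: int = 0
    n_undefined: int = 0

    def passed(self, landmark: str) -> bool:
        return bool(self.per_length.loc[landmark, "pass"])


def repeatability_cov(
    table: pd.DataFrame,
    lengths: Sequence[str] = LANDMARKS,
    threshold_percent: float = 5.0,
) -> CovReport:
    """Coefficient of variation of replicate landmark placements.

    Per section and landmark, COV = 100 · sample sd / mean over replicates;
    the report aggregates the mean and sd of COV per landmark across
    sections and gates each landmark at ``threshold_percent``.
    """
    counts = table.groupby("section_id").size()
    if (counts < 2).any():
        bad = counts[counts < 2].index[0]
        raise ValueError(f"section {bad!r} has fewer than 2 replicates")
    n_undefined = 0
    rows = {}
    grouped = table.groupby("section_id")
    covs: dict[str, list[float]] = {lm: [] for lm in lengths}
    for _, g in grouped:
        for lm in lengths:
            vals = g[lm].to_numpy(dtype=float)
            m = vals.mean()
            if m == 0:
                covs[lm].append(math.nan)
                n_undefined += 1
            else:
                covs[lm].append(100.0 * vals.std(ddof=1) / m)
    for lm in lengths:
        arr = np.asarray(covs[lm], dtype=float)
        mean_cov = float(np.nanmean(arr)) if np.any(~np.isnan(arr)) else math.nan
        sd_cov = float(np.nanstd(arr, ddof=1)) if np.sum(~np.isnan(arr)) > 1 else math.nan
        rows[lm] = {
            "mean_cov_percent": mean_cov,
            "sd_cov_percent": sd_cov,
            "pass": bool(mean_cov < threshold_percent) if not math.isnan(mean_cov) else False,
        }
    report = pd.DataFrame.from_dict(rows, orient="index")
    report.index.name = "length"
    return CovReport(
        per_length=report,
        threshold_percent=threshold_percent,
        n_sections=len(grouped),
        n_undefined=n_undefined,
    )


# ---------------------------------------------------------------------------
# summaries


@dataclass
class GroupSummary:
    """mean ± sd [min, max] summary of one group of values."""

    n: int
    mean: float
    sd: float  # NaN for n = 1 (sample sd undefined)
    min: float
    max: float

    @property
    def formatted(self) -> str:
        sd = "NA" if math.isnan(self.sd) else f"{self.sd:.2f}"
        return f"{self.mean:.2f} ± {sd} [{self.min:.2f}, {self.max:.2f}]"


def summarize(values: Iterable[float]) -> GroupSummary:
    """Summarize a group as mean ± sample sd (n−1) with range."""
    arr = np.asarray([v for v in values if not math.isnan(float(v))], dtype=float)
    if arr.size == 0:
        raise ValueError("summarize requires at least one finite value")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else math.nan
    return GroupSummary(
        n=int(arr.size),
        mean=float(arr.mean()),
        sd=sd,
        min=float(arr.min()),
        max=float(arr.max()),
    )
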