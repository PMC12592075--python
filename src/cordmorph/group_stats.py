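"""Group-comparison statistics for cohort landmark tables.

Implements the study's statistics layer: Shapiro–Wilk-gated two-group tests
(Student's t when both groups look normal, Wilcoxon–Mann–Whitney otherwise),
a one-way ANOVA screen feeding a MANOVA (Pillai's trace) on the significant
parameters, Kendall tau-b correlation matrices with banded interpretation,
and star-coded p-values including a trend marker:

    p < 0.001 → "***",  p < 0.01 → "**",  p < 0.05 → "*",  p < 0.1 → "●"

Boundary p-values fall into the weaker adjacent tier.  No multiplicity
correction is applied by default; sections are the statistical unit.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.multivariate.manova import MANOVA

__all__ = [
    "TestResult",
    "CorrelationMatrix",
    "star_code",
    "compare_two_groups",
    "anova_effect",
    "manova_screen",
    "kendall_matrix",
    "kendall_tau",
    "correlation_band",
    "region_cascade",
]

TREND_MARK = "●"  # ● marginal trend, 0.05 <= p < 0.1


def star_code(p: float) -> str:
    """Star coding of a p-value; pure and total on [0, 1]."""
    if math.isnan(p) or not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p!r} outside [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return TREND_MARK
    return ""


@dataclass
class TestResult:
    """Outcome of one hypothesis test, with star coding attached."""

    test_name: str  # student_t | wilcoxon | anova | manova_pillai | shapiro | kendall
    statistic: float
    p_value: float
    group_sizes: tuple[int, ...] = ()
    detail: dict = field(default_factory=dict)

    @property
    def stars(self) -> str:
        return star_code(self.p_value)


def compare_two_groups(
    x: Sequence[float],
    y: Sequence[float],
    alpha: float = 0.05,
    equal_var: bool = True,
) -> TestResult:
    """Normality-gated two-group comparison.

    Shapiro–Wilk on each group; if both are compatible with normality
    (p ≥ alpha) a two-sided Student t-test is used, otherwise a two-sided
    Wilcoxon–Mann–Whitney test.  ``equal_var=False`` selects Welch's t.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("each group needs n >= 3 for the Shapiro-Wilk gate")
    p_sh_x = float(stats.shapiro(x).pvalue)
    p_sh_y = float(stats.shapiro(y).pvalue)
    normal = p_sh_x >= alpha and p_sh_y >= alpha
    if normal:
        res = stats.ttest_ind(x, y, equal_var=equal_var)
        name = "student_t"
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided")
        name = "wilcoxon"
    return TestResult(
        test_name=name,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        group_sizes=(int(x.size), int(y.size)),
        detail={"shapiro_p": (p_sh_x, p_sh_y), "alpha": alpha},
    )


def anova_effect(table: pd.DataFrame, response: str, factor: str) -> TestResult:
    """One-way ANOVA of ``response`` across the levels of ``factor``."""
    groups = [g[response].to_numpy(dtype=float) for _, g in table.groupby(factor, observed=True)]
    if len(groups) < 2:
        raise ValueError(f"factor {factor!r} needs at least 2 levels")
    for g in groups:
        if g.size < 2:
            raise ValueError(f"every level of {factor!r} needs n >= 2")
    res = stats.f_oneway(*groups)
    return TestResult(
        test_name="anova",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        group_sizes=tuple(int(g.size) for g in groups),
    )


def manova_screen(
    table: pd.DataFrame, responses: Sequence[str], factor: str
) -> TestResult:
    """MANOVA (Pillai's trace) of several responses against one factor.

    With a single response this reduces to the one-way ANOVA.  A singular
    response covariance raises a ValueError naming the most collinear pair.
    """
    responses = list(responses)
    if not responses:
        raise ValueError("manova_screen needs at least one response")
    if len(responses) == 1:
        res = anova_effect(table, responses[0], factor)
        res.test_name = "manova_pillai"
        return res
    sub = table[responses].to_numpy(dtype=float)
    corr = np.corrcoef(sub, rowvar=False)
    formula = " + ".join(responses) + f" ~ C({factor})"
    try:
        mv = MANOVA.from_formula(formula, data=table)
        out = mv.mv_test()
    except np.linalg.LinAlgError as exc:
        i, j = _most_collinear_pair(corr)
        raise ValueError(
            f"singular response covariance; most collinear pair: "
            f"{responses[i]} / {responses[j]}"
        ) from exc
    np.fill_diagonal(corr, 0.0)
    if np.nanmax(np.abs(corr)) > 1 - 1e-12:
        i, j = _most_collinear_pair(np.corrcoef(sub, rowvar=False))
        raise ValueError(
            f"singular response covariance; most collinear pair: "
            f"{responses[i]} / {responses[j]}"
        )
    stat = out.results[f"C({factor})"]["stat"]
    row = stat.loc["Pillai's trace"]
    return TestResult(
        test_name="manova_pillai",
        statistic=float(row["F Value"]),
        p_value=float(row["Pr > F"]),
        group_sizes=tuple(
            int(n) for n in table.groupby(factor, observed=True).size()
        ),
        detail={"pillai_trace": float(row["Value"]), "responses": responses},
    )


def _most_collinear_pair(corr: np.ndarray) -> tuple[int, int]:
    c = np.abs(corr.copy())
    np.fill_diagonal(c, 0.0)
    return tuple(int(v) for v in np.unravel_index(np.nanargmax(c), c.shape))


# ---------------------------------------------------------------------------
# correlations


def correlation_band(tau: float) -> str:
    """Interpretation band of a correlation coefficient's magnitude."""
    if math.isnan(tau):
        return "undefined"
    t = abs(tau)
    if t >= 1.0 - 1e-12:
        return "perfect"
    if t >= 0.7:
        return "highly strong"
    if t >= 0.5:
        return "strong"
    if t >= 0.3:
        return "moderate"
    if t >= 0.1:
        return "low"
    return "negligible"


def kendall_tau(x, y) -> tuple[float, float]:
    """Kendall tau-b (tie-corrected) and its p-value for one pair."""
    res = stats.kendalltau(np.asarray(x, dtype=float), np.asarray(y, dtype=float))
    return float(res.statistic), float(res.pvalue)


@dataclass
class CorrelationMatrix:
    """Pairwise Kendall tau-b between parameters, with band labels."""

    parameters: tuple[str, ...]
    tau: np.ndarray
    p_values: np.ndarray

    def band(self, a: str, b: str) -> str:
        i = self.parameters.index(a)
        j = self.parameters.index(b)
        return correlation_band(self.tau[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.tau, index=self.parameters, columns=self.parameters)


def kendall_matrix(table: pd.DataFrame, parameters: Sequence[str]) -> CorrelationMatrix:
    """Kendall tau-b correlation matrix over the given columns.

    Constant columns have undefined tau (NaN) against every partner.
    Requires ≥ 2 parameters and ≥ 3 rows.
    """
    parameters = tuple(parameters)
    if len(parameters) < 2:
        raise ValueError("need at least two parameters")
    if len(table) < 3:
        raise ValueError("need at least three rows")
    k = len(parameters)
    tau = np.eye(k)
    pvals = np.zeros((k, k))
    cols = {p: table[p].to_numpy(dtype=float) for p in parameters}
    for i, j in itertools.combinations(range(k), 2):
        a, b = cols[parameters[i]], cols[parameters[j]]
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            t, p = math.nan, math.nan
        else:
            t, p = kendall_tau(a, b)
        tau[i, j] = tau[j, i] = t
        pvals[i, j] = pvals[j, i] = p
    return CorrelationMatrix(parameters=parameters, tau=tau, p_values=pvals)


# ---------------------------------------------------------------------------
# cascade driver


def region_cascade(
    table: pd.DataFrame,
    responses: Sequence[str],
    factor: str = "region",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """ANOVA screen per response, then MANOVA on the significant ones.

    Mirrors the two-stage design: every response is screened with a one-way
    ANOVA against ``factor``; only responses with ANOVA p < alpha enter the
    follow-up MANOVA (one per response, against the remaining significant
    set).  Returns a table with ANOVA F/p and, for screened-in responses,
    the MANOVA Pillai F/p.
    """
    rows = []
    significant: list[str] = []
    anovas: dict[str, TestResult] = {}
    for resp in responses:
        res = anova_effect(table, resp, factor)
        anovas[resp] = res
        if res.p_value < alpha:
            significant.append(resp)
    manova_res: TestResult | None = None
    if significant:
        manova_res = manova_screen(table, significant, factor)
    for resp in responses:
        res = anovas[resp]
        entered = resp in significant
        rows.append(
            {
                "response": resp,
                "anova_F": res.statistic,
                "anova_p": res.p_value,
                "anova_stars": res.stars,
                "entered_manova": entered,
                "manova_F": manova_res.statistic if entered else math.nan,
                "manova_p": manova_res.p_value if entered else math.nan,
            }
        )
    return pd.DataFrame(rows)
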