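"""Star coding, gated two-group tests, ANOVA/MANOVA cascade, Kendall tau."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from cordmorph.group_stats import (
    anova_effect,
    compare_two_groups,
    correlation_band,
    kendall_matrix,
    manova_screen,
    region_cascade,
    star_code,
)
from cordmorph.synthetic import CohortSpec, generate_cohort


class TestStarCode:
    @pytest.mark.parametrize(
        "p,stars",
        [
            (2.49e-4, "***"),
            (0.004, "**"),
            (0.03, "*"),
            (0.06, "●"),
            (0.5, ""),
            # boundaries fall into the weaker adjacent tier
            (0.001, "**"),
            (0.01, "*"),
            (0.05, "●"),
            (0.1, ""),
            (0.0, "***"),
            (1.0, ""),
        ],
    )
    def test_mapping(self, p, stars):
        assert star_code(p) == stars

    @pytest.mark.parametrize("p", [-0.1, 1.5, math.nan])
    def test_out_of_range_rejected(self, p):
        with pytest.raises(ValueError):
            star_code(p)


class TestCompareTwoGroups:
    def test_identical_groups_t_zero_p_one(self):
        res = compare_two_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.test_name == "student_t"
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        assert res.stars == ""

    def test_normal_groups_route_to_student_t(self):
        rng = np.random.default_rng(2)
        res = compare_two_groups(rng.normal(0, 1, 40), rng.normal(0, 1, 40))
        assert res.test_name == "student_t"

    def test_lognormal_group_routes_to_wilcoxon(self):
        rng = np.random.default_rng(3)
        x = rng.normal(10, 1, 60)
        y = np.exp(rng.normal(0, 1.5, 60))  # heavily skewed: Shapiro gate fires
        res = compare_two_groups(x, y)
        assert res.test_name == "wilcoxon"
        assert min(res.detail["shapiro_p"]) < 0.05

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_two_groups([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_detects_planted_shift(self):
        rng = np.random.default_rng(4)
        res = compare_two_groups(rng.normal(0, 1, 100), rng.normal(1, 1, 100))
        assert res.p_value < 0.001 and res.stars == "***"


class TestAnova:
    def frame(self, groups):
        return pd.DataFrame(
            {
                "y": np.concatenate(list(groups.values())),
                "g": np.repeat(list(groups), [len(v) for v in groups.values()]),
            }
        )

    def test_identical_groups_f_zero(self):
        res = anova_effect(self.frame({"a": [1.0, 2, 3], "b": [1.0, 2, 3]}), "y", "g")
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_planted_effect_detected(self):
        rng = np.random.default_rng(5)
        groups = {k: rng.normal(mu, 1, 50) for k, mu in [("a", 0), ("b", 5), ("c", 0)]}
        res = anova_effect(self.frame(groups), "y", "g")
        assert res.p_value < 0.001

    def test_underpopulated_level_rejected(self):
        with pytest.raises(ValueError):
            anova_effect(self.frame({"a": [1.0], "b": [1.0, 2]}), "y", "g")


class TestManova:
    def frame(self, n=60, effect=0.0, seed=0):
        rng = np.random.default_rng(seed)
        g = np.repeat(["a", "b", "c"], n)
        x = rng.normal(0, 1, 3 * n) + effect * (g == "b")
        y = rng.normal(0, 1, 3 * n) + effect * (g == "c")
        return pd.DataFrame({"g": g, "x": x, "y": y})

    def test_single_response_reduces_to_anova(self):
        df = self.frame()
        m = manova_screen(df, ["x"], "g")
        a = anova_effect(df, "x", "g")
        assert m.test_name == "manova_pillai"
        assert m.p_value == pytest.approx(a.p_value, rel=1e-9)
        assert m.statistic == pytest.approx(a.statistic, rel=1e-9)

    def test_planted_multivariate_shift_detected(self):
        res = manova_screen(self.frame(effect=1.5, seed=1), ["x", "y"], "g")
        assert res.test_name == "manova_pillai"
        assert res.p_value < 0.001

    def test_null_p_is_not_extreme(self):
        res = manova_screen(self.frame(seed=2), ["x", "y"], "g")
        assert 0.001 < res.p_value <= 1.0

    def test_collinear_responses_error_names_pair(self):
        df = self.frame()
        df["z"] = 2.0 * df["x"]
        with pytest.raises(ValueError, match="x / z"):
            manova_screen(df, ["x", "y", "z"], "g")


def kendall_tau_bruteforce(x, y):
    """Pair-counting oracle: tau-b = (C - D) / sqrt((n0 - n1)(n0 - n2))."""
    n = len(x)
    conc = disc = tx = ty = 0
    for i, j in itertools.combinations(range(n), 2):
        a = np.sign(x[i] - x[j])
        b = np.sign(y[i] - y[j])
        if a == 0 and b == 0:
            tx += 1
            ty += 1
        elif a == 0:
            tx += 1
        elif b == 0:
            ty += 1
        elif a == b:
            conc += 1
        else:
            disc += 1
    n0 = n * (n - 1) // 2
    denom = math.sqrt((n0 - tx) * (n0 - ty))
    return (conc - disc) / denom if denom else math.nan


class TestKendall:
    def matrix_tau(self, x, y):
        df = pd.DataFrame({"x": x, "y": y})
        return kendall_matrix(df, ["x", "y"]).tau[0, 1]

    def test_perfect_and_inverse(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert self.matrix_tau(x, x) == pytest.approx(1.0)
        assert self.matrix_tau(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_single_swap_gives_two_thirds(self):
        # C=5, D=1 over 6 pairs -> (5-1)/6 = 2/3
        assert self.matrix_tau([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(2 / 3)

    def test_matches_bruteforce_on_permutations(self):
        x = list(range(6))
        for perm in itertools.permutations(range(6)):
            assert self.matrix_tau(x, list(perm)) == pytest.approx(
                kendall_tau_bruteforce(x, list(perm)), abs=1e-12
            )

    def test_matches_bruteforce_with_ties(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            x = rng.integers(0, 4, 8).astype(float)
            y = rng.integers(0, 4, 8).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            assert self.matrix_tau(x, y) == pytest.approx(
                kendall_tau_bruteforce(x, y), abs=1e-12
            )

    def test_constant_column_undefined(self):
        df = pd.DataFrame({"x": [1.0, 2, 3], "y": [5.0, 5, 5]})
        mat = kendall_matrix(df, ["x", "y"])
        assert math.isnan(mat.tau[0, 1])
        assert mat.band("x", "y") == "undefined"

    def test_matrix_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("abcd"))
        mat = kendall_matrix(df, list("abcd"))
        assert np.allclose(mat.tau, mat.tau.T)
        assert np.allclose(np.diag(mat.tau), 1.0)

    @pytest.mark.parametrize(
        "tau,band",
        [
            (0.05, "negligible"), (0.2, "low"), (0.4, "moderate"),
            (0.6, "strong"), (0.8, "highly strong"), (1.0, "perfect"),
            (-0.6, "strong"),
        ],
    )
    def test_band_labels(self, tau, band):
        assert correlation_band(tau) == band


class TestCascade:
    def test_only_significant_anova_enters_manova(self):
        spec = CohortSpec(
            n_animals_per_cell=1,
            sections_per_segment=40,
            ages=("3wo",),
            sexes=("F",),
            region_effects={"cervical": {"T": 300.0, "AW": 250.0}},
            seed=10,
        )
        table, _ = generate_cohort(spec)
        out = region_cascade(table, ["T", "AW", "PW", "LDH"], "region")
        entered = set(out.loc[out.entered_manova, "response"])
        assert {"T", "AW"} <= entered
        for _, row in out.iterrows():
            if not row.entered_manova:
                assert row.anova_p >= 0.05 and math.isnan(row.manova_p)
            else:
                assert row.anova_p < 0.05 and not math.isnan(row.manova_p)
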