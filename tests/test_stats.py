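import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ojiptools.errors import SingularParameterError, UsageError
from ojiptools.io import GroupTable
from ojiptools.stats import (
    correlation_matrix,
    correlation_stars,
    one_way_anova_lsd,
    relative_profile,
    two_way_anova,
    variability,
    variability_from_table,
)


def make_table(cell_values: dict[tuple[str, str], list[float]], trait="y") -> GroupTable:
    records = []
    for (variety, treatment), values in cell_values.items():
        for rep, value in enumerate(values, start=1):
            records.append((variety, treatment, rep, trait, value))
    return GroupTable.from_records(records)


def one_factor_table(groups: dict[str, list[float]], trait="y") -> GroupTable:
    return make_table({("V1", g): vals for g, vals in groups.items()}, trait=trait)


class TestVariability:
    def test_chl_b_published_means(self):
        # treatment means of the tolerant variety's Chl b: V = (1.08-0.40)/1.08
        res = variability("chl_b", {"A": dict(zip("cdef", [0.40, 0.57, 0.59, 1.08])),
                                    "B": dict(zip("cdef", [0.37, 0.56, 0.98, 0.47]))})
        assert res.V_per_variety["A"] == pytest.approx(0.62963, abs=1e-4)
        assert res.V_per_variety["B"] == pytest.approx(0.62245, abs=1e-4)
        assert res.delta_V == pytest.approx(abs(0.62963 - 0.62245), abs=1e-4)

    def test_constant_means(self):
        res = variability("x", {"A": {"a": 2.0, "b": 2.0}, "B": {"a": 1.0, "b": 2.0}})
        assert res.V_per_variety["A"] == 0.0

    def test_simple_arithmetic(self):
        res = variability("x", {"A": {"a": 1.0, "b": 2.0, "c": 4.0},
                                "B": {"a": 1.0, "b": 1.0, "c": 1.0}})
        assert res.V_per_variety["A"] == pytest.approx(0.75, rel=1e-12)

    def test_scale_invariance(self):
        means = {"A": {"a": 0.4, "b": 1.1, "c": 0.9}, "B": {"a": 0.2, "b": 0.5, "c": 0.3}}
        scaled = {v: {t: 7.3 * m for t, m in tm.items()} for v, tm in means.items()}
        assert variability("x", means).delta_V == pytest.approx(
            variability("x", scaled).delta_V, rel=1e-12
        )

    def test_nonpositive_max(self):
        with pytest.raises(ValueError):
            variability("x", {"A": {"a": -1.0, "b": -2.0}, "B": {"a": 1.0, "b": 2.0}})

    def test_from_table_uses_replicate_means(self):
        table = make_table({("A", "0h"): [1.0, 3.0], ("A", "4h"): [4.0, 4.0],
                            ("B", "0h"): [1.0, 1.0], ("B", "4h"): [2.0, 2.0]})
        res = variability_from_table(table, "y")
        assert res.V_per_variety["A"] == pytest.approx(0.5)  # means 2 and 4
        assert res.V_per_variety["B"] == pytest.approx(0.5)


class TestOneWayAnovaLsd:
    def test_identical_groups_share_a_letter(self):
        table = one_factor_table({g: [5.0, 5.1, 4.9] for g in ("0h", "4h", "8h")})
        res = one_way_anova_lsd(table, "y")
        assert set(res.groups["letters"]) == {"a"}

    def test_one_outlying_group(self):
        rng = np.random.default_rng(0)
        groups = {"g1": list(10 + 0.01 * rng.standard_normal(3)),
                  "g2": list(10 + 0.01 * rng.standard_normal(3)),
                  "g3": list(50 + 0.01 * rng.standard_normal(3))}
        res = one_way_anova_lsd(one_factor_table(groups), "y")
        letters = dict(zip(res.groups["group"], res.groups["letters"]))
        assert letters["g3"] == "a"  # largest mean gets "a"
        assert letters["g1"] == letters["g2"] == "b"

    def test_group_of_one_rejected(self):
        with pytest.raises(UsageError, match="n < 2"):
            one_way_anova_lsd(one_factor_table({"a": [1.0], "b": [1.0, 2.0]}), "y")

    def test_zero_variance_distinct_means(self):
        res = one_way_anova_lsd(
            one_factor_table({"a": [1.0, 1.0], "b": [2.0, 2.0], "c": [3.0, 3.0]}), "y"
        )
        assert len(set(res.groups["letters"])) == 3

    @pytest.mark.parametrize("seed", range(25))
    def test_letters_match_pairwise_lsd_oracle(self, seed):
        """Sharing a letter must coincide exactly with pairwise LSD acceptance."""
        rng = np.random.default_rng(seed)
        groups = {
            f"g{i}": list(rng.normal(rng.choice([0.0, 0.4, 1.0]), 0.5, size=4))
            for i in range(4)
        }
        res = one_way_anova_lsd(one_factor_table(groups), "y", alpha=0.05)
        letters = dict(zip(res.groups["group"], res.groups["letters"]))
        # independent pairwise decisions from pooled-variance t tests
        arrs = {g: np.asarray(v) for g, v in groups.items()}
        mse = np.mean([a.var(ddof=1) for a in arrs.values()])
        dfe = sum(len(a) - 1 for a in arrs.values())
        for ga, gb in itertools.combinations(arrs, 2):
            a, b = arrs[ga], arrs[gb]
            t = abs(a.mean() - b.mean()) / np.sqrt(mse * (1 / len(a) + 1 / len(b)))
            significant = 2 * sps.t.sf(t, dfe) < 0.05
            share = bool(set(letters[ga]) & set(letters[gb]))
            assert share == (not significant), (ga, gb, letters)


class TestTwoWayAnova:
    def test_equal_cell_means_give_zero_f(self):
        table = make_table({(v, t): [3.0, 3.0, 3.0]
                            for v in ("A", "B") for t in ("0h", "4h")})
        res = two_way_anova(table, "y")
        effects = res.table.set_index("effect")
        assert (effects.loc[["variety", "treatment", "varietyxtreatment"], "F"] == 0).all()

    def test_additive_treatment_effect_detected(self):
        rng = np.random.default_rng(1)
        table = make_table({
            (v, t): list(10.0 + (5.0 if t == "4h" else 0.0) + 0.3 * rng.standard_normal(3))
            for v in ("A", "B") for t in ("0h", "4h")
        })
        effects = two_way_anova(table, "y").table.set_index("effect")
        assert effects.loc["treatment", "stars"] == "**"
        assert effects.loc["variety", "stars"] == "NS"

    def test_missing_cell_rejected(self):
        records = [("A", "0h", r, "y", 1.0) for r in (1, 2)]
        records += [("A", "4h", r, "y", 1.0) for r in (1, 2)]
        records += [("B", "0h", r, "y", 1.0) for r in (1, 2)]
        records += [("B", "4h", 1, "y", 1.0)]  # unbalanced cell
        with pytest.raises(UsageError):
            two_way_anova(GroupTable.from_records(records), "y")

    def test_sums_of_squares_decompose(self):
        rng = np.random.default_rng(2)
        table = make_table({(v, t): list(rng.normal(size=3))
                            for v in "AB" for t in ("0h", "4h", "8h", "24h")})
        res = two_way_anova(table, "y").table.set_index("effect")
        y = table.df["value"].to_numpy()
        ss_total = ((y - y.mean()) ** 2).sum()
        assert res["ss"].sum() == pytest.approx(ss_total, rel=1e-9)

    def test_against_statsmodels_type1(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(3)
        table = make_table({(v, t): list(rng.normal(float(hash((v, t)) % 5), 1.0, size=3))
                            for v in "AB" for t in ("0h", "4h", "8h")})
        res = two_way_anova(table, "y").table.set_index("effect")
        df = table.df.rename(columns={"value": "y"})
        fit = smf.ols("y ~ C(variety) * C(treatment)", data=df).fit()
        ref = sm.stats.anova_lm(fit, typ=1)
        assert res.loc["variety", "F"] == pytest.approx(ref.loc["C(variety)", "F"], rel=1e-9)
        assert res.loc["treatment", "F"] == pytest.approx(ref.loc["C(treatment)", "F"], rel=1e-9)
        assert res.loc["varietyxtreatment", "p"] == pytest.approx(
            ref.loc["C(variety):C(treatment)", "PR(>F)"], rel=1e-9
        )


class TestRelativeProfile:
    def test_control_maps_to_one(self):
        table = make_table({("A", "0h"): [2.0, 2.2], ("A", "4h"): [3.0, 3.2],
                            ("B", "0h"): [1.0, 1.2], ("B", "4h"): [0.8, 0.6]})
        prof = relative_profile(table, "0h").df.set_index(["variety", "treatment"])["value"]
        assert prof[("A", "0h")] == 1.0
        assert prof[("B", "0h")] == 1.0
        assert prof[("A", "4h")] == pytest.approx(3.1 / 2.1, rel=1e-12)
        assert prof[("B", "4h")] == pytest.approx(0.7 / 1.1, rel=1e-12)

    def test_zero_control_mean(self):
        table = make_table({("A", "0h"): [1.0, -1.0], ("A", "4h"): [1.0, 1.0]})
        with pytest.raises(SingularParameterError):
            relative_profile(table, "0h")

    def test_missing_control(self):
        table = make_table({("A", "4h"): [1.0, 1.0]})
        with pytest.raises(UsageError):
            relative_profile(table, "0h")


class TestCorrelationMatrix:
    def test_exact_linear_relation(self):
        records = []
        for rep, x in enumerate(np.linspace(0.0, 7.0, 8), start=1):
            records.append(("A", "0h", rep, "x", float(x)))
            records.append(("A", "0h", rep, "y", float(2 * x + 1)))
        corr = correlation_matrix(GroupTable.from_records(records))
        assert corr.r.loc["x", "y"] == pytest.approx(1.0, rel=1e-12)
        assert corr.r.loc["x", "x"] == 1.0
        assert corr.stars.loc["x", "y"] == "***"

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(4)
        traits = [f"t{i}" for i in range(5)]
        records = []
        data = {}
        for trait in traits:
            data[trait] = rng.normal(size=12)
            for rep, v in enumerate(data[trait], start=1):
                records.append(("A", "0h", rep, trait, float(v)))
        corr = correlation_matrix(GroupTable.from_records(records))
        n = 12
        for ta, tb in itertools.combinations(traits, 2):
            x, y = data[ta], data[tb]
            xc, yc = x - x.mean(), y - y.mean()
            r = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
            t = r * np.sqrt((n - 2) / (1 - r * r))
            p = 2 * sps.t.sf(abs(t), n - 2)
            assert corr.r.loc[ta, tb] == pytest.approx(r, abs=1e-12)
            assert corr.p.loc[ta, tb] == pytest.approx(p, rel=1e-9)
            assert corr.r.loc[tb, ta] == corr.r.loc[ta, tb]

    def test_star_thresholds(self):
        assert correlation_stars(0.0005) == "***"
        assert correlation_stars(0.005) == "**"
        assert correlation_stars(0.03) == "*"
        assert correlation_stars(0.07) == "·"
        assert correlation_stars(0.5) == ""
        assert correlation_stars(float("nan")) == ""

    def test_constant_trait_warns(self):
        records = [("A", "0h", r, "x", float(r)) for r in (1, 2, 3)]
        records += [("A", "0h", r, "c", 1.0) for r in (1, 2, 3)]
        with pytest.warns(UserWarning, match="constant"):
            corr = correlation_matrix(GroupTable.from_records(records))
        assert np.isnan(corr.r.loc["x", "c"])

    def test_too_few_observations(self):
        records = [("A", "0h", r, t, float(r)) for r in (1, 2) for t in ("x", "y")]
        with pytest.raises(UsageError, match="fewer than 3"):
            correlation_matrix(GroupTable.from_records(records))
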