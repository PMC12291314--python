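"""Comparative statistics: variability, ANOVA + LSD letters, correlations.

All tests are classical fixed-effects procedures on tidy
:class:`~ojiptools.io.GroupTable` data:

* range variability V = (max - min)/max over treatment means, and the
  between-variety difference delta-V;
* one-way ANOVA with unadjusted Fisher-LSD pairwise comparisons summarized
  as a compact letter display (insert-and-absorb algorithm, letter "a" on
  the largest mean);
* balanced two-way fixed-effects ANOVA with interaction, mapped to the
  usual significance stars;
* trait ratios relative to a control group;
* pairwise-complete Pearson correlation matrices with significance stars
  at 0.001 / 0.01 / 0.05 / 0.10.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import SingularParameterError, UsageError
from .io import GroupTable

__all__ = [
    "VariabilityResult",
    "AnovaLetters",
    "TwoWayAnovaResult",
    "CorrelationMatrix",
    "variability",
    "variability_from_table",
    "one_way_anova_lsd",
    "two_way_anova",
    "relative_profile",
    "correlation_matrix",
    "correlation_stars",
]


# ---------------------------------------------------------------------------
# variability

@dataclass(frozen=True)
class VariabilityResult:
    trait: str
    V_per_variety: Mapping[str, float]
    delta_V: float


def _range_variability(means: Sequence[float]) -> float:
    m = np.asarray(means, dtype=float)
    if len(m) < 2:
        raise UsageError("variability needs >= 2 treatment means")
    mx = m.max()
    if mx <= 0:
        raise ValueError(f"max of means must be > 0, got {mx:g}")
    return float((mx - m.min()) / mx)


def variability(
    trait: str,
    means: Mapping[str, Mapping[str, float]],
    variety_pair: tuple[str, str] | None = None,
) -> VariabilityResult:
    """V = (max - min)/max over the treatment means of each variety.

    ``means`` maps variety -> treatment -> mean. ``delta_V`` is the absolute
    difference between the two varieties of ``variety_pair`` (defaults to
    the only two varieties present).
    """
    v = {var: _range_variability(list(tm.values())) for var, tm in means.items()}
    if variety_pair is None:
        if len(v) != 2:
            raise UsageError("variety_pair required unless exactly 2 varieties present")
        variety_pair = tuple(sorted(v))  # type: ignore[assignment]
    a, b = variety_pair
    return VariabilityResult(trait=trait, V_per_variety=v, delta_V=abs(v[a] - v[b]))


def variability_from_table(
    table: GroupTable, trait: str, variety_pair: tuple[str, str] | None = None
) -> VariabilityResult:
    df = table.subset(trait=trait)
    if df.empty:
        raise UsageError(f"trait {trait!r} not in table")
    means = (
        df.groupby(["variety", "treatment"])["value"].mean().unstack().T.to_dict()
    )
    return variability(trait, means, variety_pair)


# ---------------------------------------------------------------------------
# one-way ANOVA + Fisher LSD compact letter display

@dataclass
class AnovaLetters:
    """Per-group means with LSD letter codes; shared letter <=> not different."""

    trait: str
    alpha: float
    F: float
    p: float
    groups: pd.DataFrame  # columns: group, mean, sd, n, letters


def _compact_letter_display(
    names: Sequence[str], means: Sequence[float], significant: set[tuple[int, int]]
) -> list[str]:
    """Insert-and-absorb letter assignment.

    ``significant`` holds index pairs (i, j) that differ. Groups are indexed
    in the caller's order; letters are issued so that the group with the
    largest mean carries "a".
    """
    k = len(names)
    order = sorted(range(k), key=lambda i: -means[i])
    columns: list[set[int]] = [set(range(k))]
    for a in range(k):
        for b in range(a + 1, k):
            if (a, b) not in significant:
                continue
            new_cols: list[set[int]] = []
            for col in columns:
                if a in col and b in col:
                    new_cols.append(col - {a})
                    new_cols.append(col - {b})
                else:
                    new_cols.append(col)
            # absorb: drop any column contained in another
            columns = [
                c
                for i, c in enumerate(new_cols)
                if c and not any(c < d or (c == d and i > j) for j, d in enumerate(new_cols))
            ]
    # letter columns ordered by the rank of the best mean they contain
    rank = {g: r for r, g in enumerate(order)}
    columns.sort(key=lambda c: min(rank[g] for g in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = ["" for _ in range(k)]
    for li, col in enumerate(columns):
        for g in sorted(col, key=lambda g: rank[g]):
            letters[g] += alphabet[li % 26]
    return letters


def one_way_anova_lsd(
    table: GroupTable,
    trait: str,
    grouping: str = "treatment",
    variety: str | None = None,
    alpha: float = 0.05,
) -> AnovaLetters:
    """One-way fixed-effects ANOVA with Fisher-LSD letter groups.

    Pairwise comparisons use t-tests on the pooled within-group mean square
    and its error degrees of freedom (classic unadjusted LSD). With zero
    pooled variance, any difference in means counts as significant.
    """
    df = table.subset(variety=variety, trait=trait)
    if df.empty:
        raise UsageError(f"trait {trait!r} not in table")
    grouped = df.groupby(grouping)["value"]
    names = list(grouped.groups)
    if len(names) < 2:
        raise UsageError("need >= 2 groups")
    values = [grouped.get_group(g).to_numpy(dtype=float) for g in names]
    ns = np.array([len(v) for v in values])
    if (ns < 2).any():
        bad = names[int(np.argmax(ns < 2))]
        raise UsageError(f"group {bad!r} has n < 2")
    means = np.array([v.mean() for v in values])
    sds = np.array([v.std(ddof=1) for v in values])

    n_tot = int(ns.sum())
    grand = np.concatenate(values).mean()
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(((v - v.mean()) ** 2).sum() for v in values))
    df_between = len(names) - 1
    df_within = n_tot - len(names)
    mse = ss_within / df_within
    if mse > 0:
        F = (ss_between / df_between) / mse
        p = float(sps.f.sf(F, df_between, df_within))
    else:
        F = np.inf if ss_between > 0 else 0.0
        p = 0.0 if ss_between > 0 else 1.0

    significant: set[tuple[int, int]] = set()
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if mse > 0:
                se = np.sqrt(mse * (1.0 / ns[i] + 1.0 / ns[j]))
                t = abs(means[i] - means[j]) / se
                p_ij = 2.0 * float(sps.t.sf(t, df_within))
                if p_ij < alpha:
                    significant.add((i, j))
            elif means[i] != means[j]:
                significant.add((i, j))

    letters = _compact_letter_display(names, means, significant)
    groups = pd.DataFrame(
        {"group": names, "mean": means, "sd": sds, "n": ns, "letters": letters}
    )
    return AnovaLetters(trait=trait, alpha=alpha, F=float(F), p=p, groups=groups)


# ---------------------------------------------------------------------------
# balanced two-way ANOVA

@dataclass
class TwoWayAnovaResult:
    trait: str
    table: pd.DataFrame  # effect, ss, df, F, p, stars


def _effect_stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"


def two_way_anova(
    table: GroupTable,
    trait: str,
    factors: tuple[str, str] = ("variety", "treatment"),
) -> TwoWayAnovaResult:
    """Balanced two-way fixed-effects ANOVA with interaction, starred.

    Requires a full factorial with equal replication per cell; sums of
    squares are the classical decomposition (equivalent to type I on a
    balanced design). Effects map to "**" (p < 0.01), "*" (p < 0.05), "NS".
    """
    fa, fb = factors
    df = table.subset(trait=trait)
    if df.empty:
        raise UsageError(f"trait {trait!r} not in table")
    cells = df.groupby([fa, fb])["value"]
    a_levels = sorted(df[fa].unique())
    b_levels = sorted(df[fb].unique())
    counts = cells.size()
    if len(counts) != len(a_levels) * len(b_levels):
        raise UsageError("missing cells: design is not a full factorial")
    n = int(counts.iloc[0])
    if n < 2 or (counts != n).any():
        raise UsageError("cells must have equal replication with n >= 2")

    y = df["value"].to_numpy(dtype=float)
    grand = y.mean()
    a_means = df.groupby(fa)["value"].mean()
    b_means = df.groupby(fb)["value"].mean()
    cell_means = cells.mean()

    a_count, b_count = len(a_levels), len(b_levels)
    ss_a = b_count * n * float(((a_means - grand) ** 2).sum())
    ss_b = a_count * n * float(((b_means - grand) ** 2).sum())
    ss_cells = n * float(((cell_means - grand) ** 2).sum())
    ss_ab = ss_cells - ss_a - ss_b
    ss_err = float(
        sum(((v - v.mean()) ** 2).sum() for _, v in cells)
    )
    df_a, df_b = a_count - 1, b_count - 1
    df_ab = df_a * df_b
    df_err = a_count * b_count * (n - 1)
    mse = ss_err / df_err

    rows = []
    for effect, ss, dof in ((fa, ss_a, df_a), (fb, ss_b, df_b), (f"{fa}x{fb}", ss_ab, df_ab)):
        if mse > 0:
            F = (ss / dof) / mse
            p = float(sps.f.sf(F, dof, df_err))
        else:
            F = np.inf if ss > 0 else 0.0
            p = 0.0 if ss > 0 else 1.0
        rows.append(
            {"effect": effect, "ss": ss, "df": dof, "F": F, "p": p, "stars": _effect_stars(p)}
        )
    rows.append(
        {"effect": "error", "ss": ss_err, "df": df_err, "F": np.nan, "p": np.nan, "stars": ""}
    )
    return TwoWayAnovaResult(trait=trait, table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# relative-to-control profiles

def relative_profile(table: GroupTable, control_label: str) -> GroupTable:
    """Treatment-group trait means divided by the control mean, per variety.

    The output is a GroupTable with ``replicate = 0`` marking aggregated
    rows; the control treatment maps to exactly 1.0 for every trait.
    """
    df = table.df
    if control_label not in set(df["treatment"]):
        raise UsageError(f"control treatment {control_label!r} not present")
    means = (
        df.groupby(["variety", "treatment", "trait"])["value"].mean().reset_index()
    )
    control = means[means["treatment"] == control_label].set_index(["variety", "trait"])[
        "value"
    ]
    records = []
    for row in means.itertuples(index=False):
        ref = control.get((row.variety, row.trait))
        if ref is None or pd.isna(ref):
            raise UsageError(f"no control mean for {row.variety}/{row.trait}")
        if ref == 0:
            raise SingularParameterError(
                f"{row.trait}", f"zero control mean for {row.variety}/{row.trait}"
            )
        records.append((row.variety, row.treatment, 0, row.trait, row.value / ref))
    return GroupTable.from_records(records)


# ---------------------------------------------------------------------------
# Pearson correlation matrix with significance stars

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"), (0.10, "·"))


def correlation_stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    for threshold, stars in STAR_THRESHOLDS:
        if p < threshold:
            return stars
    return ""


@dataclass
class CorrelationMatrix:
    traits: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame
    n: pd.DataFrame

    def to_long(self) -> pd.DataFrame:
        rows = []
        for i, ti in enumerate(self.traits):
            for tj in self.traits[i + 1 :]:
                rows.append(
                    {
                        "trait_i": ti,
                        "trait_j": tj,
                        "r": self.r.loc[ti, tj],
                        "p": self.p.loc[ti, tj],
                        "n": self.n.loc[ti, tj],
                        "stars": self.stars.loc[ti, tj],
                    }
                )
        return pd.DataFrame(rows)


def correlation_matrix(
    table: GroupTable,
    traits: Sequence[str] | None = None,
    variety: str | None = None,
) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlations between traits.

    Observations are the (variety, treatment, replicate) units, pooled
    across treatments (and across varieties unless ``variety`` restricts
    the table). Pairs with fewer than 3 complete observations or a constant
    trait yield NaN with a warning. The diagonal is r = 1 with no test.
    """
    df = table.subset(variety=variety)
    if traits is None:
        traits = sorted(df["trait"].unique())
    wide = df.pivot_table(
        index=["variety", "treatment", "replicate"], columns="trait", values="value"
    )
    missing = [t for t in traits if t not in wide.columns]
    if missing:
        raise UsageError(f"trait(s) not in table: {missing}")
    k = len(traits)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    np.fill_diagonal(r, 1.0)
    for i in range(k):
        n[i, i] = int(wide[traits[i]].notna().sum())
        for j in range(i + 1, k):
            pair = wide[[traits[i], traits[j]]].dropna()
            n[i, j] = n[j, i] = len(pair)
            if len(pair) < 3:
                raise UsageError(
                    f"fewer than 3 paired observations for ({traits[i]}, {traits[j]})"
                )
            x = pair[traits[i]].to_numpy()
            y = pair[traits[j]].to_numpy()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                warnings.warn(
                    f"constant trait in pair ({traits[i]}, {traits[j]}); r undefined",
                    UserWarning,
                    stacklevel=2,
                )
                continue
            res = sps.pearsonr(x, y)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    stars = np.array(
        [[correlation_stars(p[i, j]) if i != j else "" for j in range(k)] for i in range(k)],
        dtype=object,
    )
    idx = list(traits)
    return CorrelationMatrix(
        traits=idx,
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        stars=pd.DataFrame(stars, index=idx, columns=idx),
        n=pd.DataFrame(n, index=idx, columns=idx),
    )
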