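"""Group-comparison statistics for behavioral cohorts.

Two-tailed Mann-Whitney U for whole-session contrasts, two-way ANOVA for
minute-by-minute (mixed between-group x within-subject) and area (social vs
non-social within subject) designs, with Tukey and Sidak post hoc
procedures. Alpha is 0.05 throughout and no multiplicity correction is
applied across the five kinematic statistics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSample",
    "AnovaTable",
    "EffectResult",
    "PosthocResult",
    "StatsInputError",
    "mann_whitney_u",
    "two_way_anova",
    "tukey_posthoc",
    "sidak_posthoc",
    "compare_cohort",
]

ALPHA = 0.05

#: combined-n threshold below which the exact Mann-Whitney null is used
EXACT_LIMIT = 16


class StatsInputError(ValueError):
    """Raised for malformed statistical inputs."""


@dataclass(frozen=True)
class GroupSample:
    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or len(v) < 1:
            raise StatsInputError("GroupSample needs a 1-D array with n >= 1")
        if not np.all(np.isfinite(v)):
            raise StatsInputError("GroupSample values must be finite")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return len(self.values)


def mann_whitney_u(
    a: GroupSample | np.ndarray,
    b: GroupSample | np.ndarray,
    exact_limit: int = EXACT_LIMIT,
) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U test.

    Returns ``(U, p)`` with ``U = min(U_a, U_b)`` from midrank sums. The p
    value is exact (full-enumeration null) when the combined sample size is
    at most ``exact_limit`` and there are no ties; otherwise the normal
    approximation with tie and continuity corrections is used. When all
    pooled values are identical, ``p = 1`` with a warning.
    """
    av = a.values if isinstance(a, GroupSample) else np.asarray(a, float)
    bv = b.values if isinstance(b, GroupSample) else np.asarray(b, float)
    if len(av) < 1 or len(bv) < 1:
        raise StatsInputError("both groups need n >= 1")
    pooled = np.concatenate([av, bv])
    ranks = sps.rankdata(pooled)
    n_a, n_b = len(av), len(bv)
    u_a = float(np.sum(ranks[:n_a]) - n_a * (n_a + 1) / 2.0)
    u_b = n_a * n_b - u_a
    u = min(u_a, u_b)
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical across both groups; p = 1")
        return u, 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    if (n_a + n_b) <= exact_limit and not has_ties:
        res = sps.mannwhitneyu(av, bv, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(
            av, bv, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return u, float(min(res.pvalue, 1.0))


@dataclass(frozen=True)
class EffectResult:
    name: str
    ss: float
    df1: int
    df2: int
    ms: float
    f: float
    p: float


@dataclass(frozen=True)
class AnovaTable:
    """Two-factor ANOVA decomposition.

    ``effects`` holds results for factor A (between groups), factor B and
    the A x B interaction. For mixed designs, ``error_within_ms``/``df`` is
    the within-subject error term used for post hoc contrasts over factor B
    levels, and ``error_between_ms``/``df`` the subject-within-group term.
    """

    design: str
    effects: dict
    error_within_ms: float
    error_within_df: int
    error_between_ms: float
    error_between_df: int
    cell_means: pd.DataFrame
    group_ns: dict

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "effect": e.name,
                "ss": e.ss,
                "df1": e.df1,
                "df2": e.df2,
                "F": e.f,
                "p": e.p,
            }
            for e in self.effects.values()
        ]
        return pd.DataFrame(rows)


def _f_p(ms_num: float, ms_den: float, df1: int, df2: int) -> tuple[float, float]:
    if ms_den <= 0:
        return math.inf if ms_num > 0 else 0.0, 0.0 if ms_num > 0 else 1.0
    f = ms_num / ms_den
    return f, float(sps.f.sf(f, df1, df2))


def two_way_anova(
    data: pd.DataFrame,
    dv: str = "value",
    between: str = "group",
    within: str = "level",
    subject: str = "subject_id",
    design: str = "mixed",
) -> AnovaTable:
    """Two-way ANOVA with factor A between groups and factor B either
    within subjects (``design='mixed'``, the default) or between
    (``design='between'``).

    Mixed designs require one complete row of factor-B levels per subject;
    the sums of squares use the classical univariate decomposition with the
    subject-within-group term as the error for A and the residual
    within-subject term as the error for B and A x B. For unbalanced group
    sizes this is the weighted-means solution.
    """
    df = data[[subject, between, within, dv]].copy()
    if df[dv].isna().any():
        raise StatsInputError("response contains missing values")
    levels_b = sorted(df[within].unique())
    groups = sorted(df[between].unique())
    a, b = len(groups), len(levels_b)
    if a < 2 or b < 2:
        raise StatsInputError("both factors need at least 2 levels")

    if design == "between":
        return _between_anova(df, dv, between, within)
    if design != "mixed":
        raise StatsInputError(f"unknown design {design!r}")

    # completeness: every subject must have exactly one value per level
    counts = df.groupby([subject, within])[dv].count().unstack(fill_value=0)
    bad = counts.index[(counts != 1).any(axis=1)].tolist()
    if bad:
        raise StatsInputError(f"incomplete within-subject rows for subjects: {bad}")

    wide = df.pivot_table(index=[subject, between], columns=within, values=dv)
    wide = wide[levels_b]
    y = wide.to_numpy(float)  # subjects x levels
    subj_group = wide.index.get_level_values(between).to_numpy()
    n_total = y.shape[0]
    grand = y.mean()
    subj_means = y.mean(axis=1)
    group_ns = {g: int(np.sum(subj_group == g)) for g in groups}
    group_means = {g: subj_means[subj_group == g].mean() for g in groups}
    level_means = y.mean(axis=0)
    cell = np.vstack([y[subj_group == g].mean(axis=0) for g in groups])  # a x b

    ss_total = float(np.sum((y - grand) ** 2))
    ss_between_subj = b * float(np.sum((subj_means - grand) ** 2))
    ss_a = b * float(sum(group_ns[g] * (group_means[g] - grand) ** 2 for g in groups))
    ss_subj = ss_between_subj - ss_a
    ss_b = n_total * float(np.sum((level_means - grand) ** 2))
    ss_cells = float(sum(group_ns[g] * np.sum((cell[i] - grand) ** 2) for i, g in enumerate(groups)))
    ss_ab = ss_cells - ss_a - ss_b
    ss_error = ss_total - ss_between_subj - ss_b - ss_ab

    df_a, df_b = a - 1, b - 1
    df_ab = df_a * df_b
    df_subj = n_total - a
    df_error = df_subj * df_b
    if df_subj <= 0 or df_error <= 0:
        raise StatsInputError("not enough subjects for a mixed ANOVA")
    ms_a, ms_b = ss_a / df_a, ss_b / df_b
    ms_ab = ss_ab / df_ab
    ms_subj = ss_subj / df_subj
    ms_error = ss_error / df_error

    f_a, p_a = _f_p(ms_a, ms_subj, df_a, df_subj)
    f_b, p_b = _f_p(ms_b, ms_error, df_b, df_error)
    f_ab, p_ab = _f_p(ms_ab, ms_error, df_ab, df_error)

    effects = {
        between: EffectResult(between, ss_a, df_a, df_subj, ms_a, f_a, p_a),
        within: EffectResult(within, ss_b, df_b, df_error, ms_b, f_b, p_b),
        "interaction": EffectResult("interaction", ss_ab, df_ab, df_error, ms_ab, f_ab, p_ab),
    }
    cell_means = pd.DataFrame(cell, index=groups, columns=levels_b)
    return AnovaTable(
        design="mixed",
        effects=effects,
        error_within_ms=ms_error,
        error_within_df=df_error,
        error_between_ms=ms_subj,
        error_between_df=df_subj,
        cell_means=cell_means,
        group_ns=group_ns,
    )


def _between_anova(df: pd.DataFrame, dv: str, factor_a: str, factor_b: str) -> AnovaTable:
    """Fully between-subjects two-way ANOVA (type III via statsmodels)."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    work = df.rename(columns={dv: "_y", factor_a: "_a", factor_b: "_b"})
    model = smf.ols("_y ~ C(_a, Sum) * C(_b, Sum)", data=work).fit()
    table = sm.stats.anova_lm(model, typ=3)
    resid = table.loc["Residual"]
    ms_err = float(resid["sum_sq"] / resid["df"])
    df_err = int(resid["df"])

    def _row(key: str, name: str) -> EffectResult:
        r = table.loc[key]
        ss, d1 = float(r["sum_sq"]), int(r["df"])
        return EffectResult(name, ss, d1, df_err, ss / d1, float(r["F"]), float(r["PR(>F)"]))

    effects = {
        factor_a: _row("C(_a, Sum)", factor_a),
        factor_b: _row("C(_b, Sum)", factor_b),
        "interaction": _row("C(_a, Sum):C(_b, Sum)", "interaction"),
    }
    groups = sorted(df[factor_a].unique())
    levels = sorted(df[factor_b].unique())
    cell = df.groupby([factor_a, factor_b])[dv].mean().unstack()
    cell = cell.loc[groups, levels]
    group_ns = df.groupby(factor_a)[dv].count().to_dict()
    return AnovaTable(
        design="between",
        effects=effects,
        error_within_ms=ms_err,
        error_within_df=df_err,
        error_between_ms=ms_err,
        error_between_df=df_err,
        cell_means=cell,
        group_ns=group_ns,
    )


@dataclass(frozen=True)
class PosthocResult:
    method: str
    comparisons: tuple  # of (contrast, estimate, p_adjusted)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"contrast": c, "estimate": e, "p_adj": p} for c, e, p in self.comparisons]
        )


def tukey_posthoc(
    means: dict,
    ns: dict,
    ms_error: float,
    df_error: int,
    pairs: list[tuple] | None = None,
) -> PosthocResult:
    """Tukey(-Kramer) studentized-range comparisons among cell means.

    ``means``/``ns`` map cell labels to means and per-cell sample sizes;
    ``ms_error``/``df_error`` come from the fitted ANOVA. The family size
    for the studentized range is the number of cells in ``means``.
    """
    labels = list(means)
    k = len(labels)
    if k < 2:
        raise StatsInputError("need at least two cells")
    if pairs is None:
        pairs = list(combinations(labels, 2))
    comps = []
    for l1, l2 in pairs:
        diff = means[l1] - means[l2]
        se = math.sqrt(ms_error / 2.0 * (1.0 / ns[l1] + 1.0 / ns[l2]))
        if se == 0:
            p = 1.0 if diff == 0 else 0.0
        else:
            q = abs(diff) / se
            p = float(sps.studentized_range.sf(q, k, df_error))
        comps.append((f"{l1} vs {l2}", float(diff), min(max(p, 0.0), 1.0)))
    return PosthocResult(method="tukey", comparisons=tuple(comps))


def sidak_posthoc(raw_ps, m: int | None = None, contrasts=None, estimates=None) -> PosthocResult:
    """Sidak adjustment ``p_adj = 1 - (1 - p_raw)**m`` clipped to [0, 1]."""
    raw = list(raw_ps)
    if m is None:
        m = len(raw)
    if m < 1:
        raise StatsInputError("m must be >= 1")
    if contrasts is None:
        contrasts = [f"comparison_{i}" for i in range(len(raw))]
    if estimates is None:
        estimates = [math.nan] * len(raw)
    comps = []
    for c, e, p in zip(contrasts, estimates, raw):
        p_adj = 1.0 - (1.0 - p) ** m
        comps.append((c, float(e), float(min(max(p_adj, 0.0), 1.0))))
    return PosthocResult(method="sidak", comparisons=tuple(comps))


# ---------------------------------------------------------------------------
# cohort-level orchestration


def _split_groups(df: pd.DataFrame, group_col: str) -> list[str]:
    groups = sorted(df[group_col].unique())
    if len(groups) != 2:
        raise StatsInputError(f"expected exactly 2 groups, got {groups}")
    return groups


def compare_cohort(
    summaries: pd.DataFrame,
    design: str,
    statistics=None,
    alpha: float = ALPHA,
) -> dict:
    """Run the paper-style group comparison over per-subject summaries.

    ``design='totals'`` expects columns ``subject_id, group, statistic,
    value`` (one value per subject and statistic) and applies Mann-Whitney
    per statistic. ``design='minutes'`` / ``design='areas'`` expect an extra
    ``level`` column (minute index or area label) and run a mixed two-way
    ANOVA per statistic, followed by Tukey (first-vs-last level within each
    group) or Sidak (the four cell contrasts) post hoc tests.

    Rows flagged ``degenerate`` (if the column is present) are excluded and
    listed in the returned ``exclusions`` log.
    """
    df = summaries.copy()
    exclusions: list[str] = []
    if "degenerate" in df.columns:
        bad = df.loc[df["degenerate"].astype(bool), "subject_id"].unique().tolist()
        exclusions = sorted(str(s) for s in bad)
        df = df[~df["subject_id"].isin(bad)]
    if "statistic" not in df.columns:
        raise StatsInputError("summaries need a 'statistic' column (long format)")
    if statistics is None:
        statistics = sorted(df["statistic"].unique())
    groups = _split_groups(df, "group")
    for g in groups:
        if df.loc[df["group"] == g, "subject_id"].nunique() < 2:
            raise StatsInputError(f"group {g!r} has fewer than 2 usable subjects")

    results: dict[str, dict] = {}
    for stat in statistics:
        sub = df[df["statistic"] == stat].dropna(subset=["value"])
        if design == "totals":
            a = sub.loc[sub["group"] == groups[0], "value"].to_numpy(float)
            b = sub.loc[sub["group"] == groups[1], "value"].to_numpy(float)
            u, p = mann_whitney_u(a, b)
            results[stat] = {
                "test": "mann_whitney_u",
                "U": u,
                "p": p,
                "significant": p < alpha,
                "group_means": {groups[0]: float(np.mean(a)), groups[1]: float(np.mean(b))},
                "group_ns": {groups[0]: len(a), groups[1]: len(b)},
            }
        elif design in ("minutes", "areas"):
            if "level" not in sub.columns:
                raise StatsInputError(f"design {design!r} needs a 'level' column")
            table = two_way_anova(
                sub, dv="value", between="group", within="level", subject="subject_id",
                design="mixed",
            )
            entry = {"test": "mixed_anova", "anova": table}
            levels = list(table.cell_means.columns)
            if design == "minutes":
                first, last = levels[0], levels[-1]
                comps = {}
                for g in groups:
                    means = {lv: float(table.cell_means.loc[g, lv]) for lv in levels}
                    ns = {lv: table.group_ns[g] for lv in levels}
                    res = tukey_posthoc(
                        means, ns, table.error_within_ms, table.error_within_df,
                        pairs=[(first, last)],
                    )
                    comps[g] = res
                entry["posthoc"] = comps
            else:  # areas: Sidak over the four standard cell contrasts
                raw_ps, names, ests = [], [], []
                for g in groups:  # within-group area contrast (paired t)
                    piv = sub[sub["group"] == g].pivot(
                        index="subject_id", columns="level", values="value"
                    )[levels]
                    d = piv[levels[0]] - piv[levels[1]]
                    t = sps.ttest_1samp(d, 0.0)
                    raw_ps.append(float(t.pvalue))
                    names.append(f"{g}: {levels[0]} vs {levels[1]}")
                    ests.append(float(d.mean()))
                for lv in levels:  # between-group contrast within each area
                    x = sub[(sub["group"] == groups[0]) & (sub["level"] == lv)]["value"]
                    y = sub[(sub["group"] == groups[1]) & (sub["level"] == lv)]["value"]
                    t = sps.ttest_ind(x, y)
                    raw_ps.append(float(t.pvalue))
                    names.append(f"{lv}: {groups[0]} vs {groups[1]}")
                    ests.append(float(x.mean() - y.mean()))
                entry["posthoc"] = sidak_posthoc(raw_ps, m=len(raw_ps), contrasts=names,
                                                 estimates=ests)
            results[stat] = entry
        else:
            raise StatsInputError(f"unknown design {design!r}")
    return {"design": design, "groups": groups, "alpha": alpha,
            "exclusions": exclusions, "results": results}


def comparison_table(report: dict) -> pd.DataFrame:
    """Flatten a compare_cohort report into a tidy frame."""
    rows = []
    for stat, entry in report["results"].items():
        if entry["test"] == "mann_whitney_u":
            rows.append({"statistic": stat, "effect": "group", "stat_value": entry["U"],
                         "p": entry["p"], "method": "mann_whitney_u"})
        else:
            for eff in entry["anova"].effects.values():
                rows.append({"statistic": stat, "effect": eff.name, "stat_value": eff.f,
                             "p": eff.p, "method": "mixed_anova_F"})
    return pd.DataFrame(rows)
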