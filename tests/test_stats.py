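import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ethokinetics.stats import (
    GroupSample,
    StatsInputError,
    compare_cohort,
    mann_whitney_u,
    sidak_posthoc,
    tukey_posthoc,
    two_way_anova,
)


def enumeration_p(a, b):
    """Exact two-sided Mann-Whitney p by enumerating rank assignments."""
    pooled = list(a) + list(b)
    n_a = len(a)
    ranks = sps.rankdata(pooled)

    def u_of(idx):
        r = sum(ranks[i] for i in idx)
        ua = r - n_a * (n_a + 1) / 2.0
        return min(ua, n_a * (len(pooled) - n_a) - ua)

    observed = u_of(range(n_a))
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        total += 1
        if u_of(idx) <= observed + 1e-12:
            count += 1
    return count / total


class TestMannWhitney:
    def test_complete_separation_small(self):
        u, p = mann_whitney_u(np.array([1.0, 2, 3]), np.array([4.0, 5, 6]))
        assert u == 0
        assert p == pytest.approx(0.1)  # 2 of C(6,3)=20 assignments per both tails

    def test_identical_groups(self):
        with pytest.warns(UserWarning):
            u, p = mann_whitney_u(np.array([2.0, 2, 2]), np.array([2.0, 2, 2]))
        assert p == 1.0

    def test_exact_matches_enumeration_8v8(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            a = rng.normal(size=8)
            b = rng.normal(0.5, size=8)
            _, p = mann_whitney_u(a, b)
            assert p == pytest.approx(enumeration_p(a, b), abs=1e-12)

    def test_all_tiefree_small_inputs(self):
        # every rank configuration for a 4 vs 4 split
        n_a, n_b = 4, 4
        values = np.arange(1.0, n_a + n_b + 1)
        for idx in itertools.combinations(range(n_a + n_b), n_a):
            a = values[list(idx)]
            b = np.delete(values, list(idx))
            _, p = mann_whitney_u(a, b)
            assert p == pytest.approx(enumeration_p(a, b), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=6), rng.normal(size=7)
        u1, p1 = mann_whitney_u(a, b)
        u2, p2 = mann_whitney_u(np.exp(a), np.exp(b))
        assert u1 == u2
        assert p1 == pytest.approx(p2)

    def test_ties_use_asymptotic(self):
        a = np.array([1.0, 2, 2, 3])
        b = np.array([2.0, 3, 3, 4])
        u, p = mann_whitney_u(a, b)
        assert 0 < p <= 1

    def test_empty_group_rejected(self):
        with pytest.raises(StatsInputError):
            mann_whitney_u(np.array([]), np.array([1.0]))


def _mixed_frame(y, groups, n_levels, level_names=None):
    """Long frame from a (subjects x levels) array."""
    rows = []
    levels = level_names or list(range(n_levels))
    for s, (row, g) in enumerate(zip(y, groups)):
        for j, lv in enumerate(levels):
            rows.append({"subject_id": f"s{s}", "group": g, "level": lv,
                         "value": float(row[j])})
    return pd.DataFrame(rows)


class TestTwoWayAnova:
    def test_identical_groups_f_near_zero(self):
        y_block = np.array([[1.0, 2.0, 3.0], [2.0, 3.0, 4.0], [1.5, 2.5, 3.5]])
        y = np.vstack([y_block, y_block])
        groups = ["a"] * 3 + ["b"] * 3
        table = two_way_anova(_mixed_frame(y, groups, 3))
        assert table.effects["group"].f == pytest.approx(0.0, abs=1e-12)
        assert table.effects["group"].p == pytest.approx(1.0)

    def test_grand_mean_shift_invariance(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=(8, 4))
        groups = ["a"] * 4 + ["b"] * 4
        t1 = two_way_anova(_mixed_frame(y, groups, 4))
        t2 = two_way_anova(_mixed_frame(y + 100.0, groups, 4))
        for k in t1.effects:
            assert t1.effects[k].f == pytest.approx(t2.effects[k].f, rel=1e-9)

    def test_hand_computed_ss_2x2_between(self):
        # 2x2 between design, n=3/cell; SS computed by hand below
        data = {
            ("a", "x"): [1.0, 2.0, 3.0],
            ("a", "y"): [2.0, 3.0, 4.0],
            ("b", "x"): [5.0, 6.0, 7.0],
            ("b", "y"): [9.0, 10.0, 11.0],
        }
        rows = []
        i = 0
        for (g, lv), vals in data.items():
            for v in vals:
                rows.append({"subject_id": f"s{i}", "group": g, "level": lv, "value": v})
                i += 1
        df = pd.DataFrame(rows)
        table = two_way_anova(df, design="between")
        # hand computation: cell means 2, 3, 6, 10; grand 5.25
        cells = {k: sum(v) / 3 for k, v in data.items()}
        grand = sum(sum(v) for v in data.values()) / 12
        ma = {g: (cells[(g, "x")] + cells[(g, "y")]) / 2 for g in ("a", "b")}
        mb = {lv: (cells[("a", lv)] + cells[("b", lv)]) / 2 for lv in ("x", "y")}
        ss_a = 6 * sum((ma[g] - grand) ** 2 for g in ma)
        ss_b = 6 * sum((mb[lv] - grand) ** 2 for lv in mb)
        ss_ab = 3 * sum(
            (cells[(g, lv)] - ma[g] - mb[lv] + grand) ** 2 for g, lv in cells
        )
        ss_err = sum(
            (v - cells[(g, lv)]) ** 2 for (g, lv), vals in data.items() for v in vals
        )
        assert table.effects["group"].ss == pytest.approx(ss_a, rel=1e-8)
        assert table.effects["level"].ss == pytest.approx(ss_b, rel=1e-8)
        assert table.effects["interaction"].ss == pytest.approx(ss_ab, rel=1e-8)
        assert table.error_within_ms * table.error_within_df == pytest.approx(ss_err, rel=1e-8)

    def test_mixed_ss_conservation_balanced(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=(10, 5))
        groups = ["a"] * 5 + ["b"] * 5
        table = two_way_anova(_mixed_frame(y, groups, 5))
        grand = y.mean()
        ss_total = ((y - grand) ** 2).sum()
        ss_model = (
            table.effects["group"].ss
            + table.effects["level"].ss
            + table.effects["interaction"].ss
            + table.error_between_ms * table.error_between_df
            + table.error_within_ms * table.error_within_df
        )
        assert ss_model == pytest.approx(ss_total, rel=1e-8)

    def test_mixed_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        y = np.vstack([rng.normal(0, 1, size=(6, 4)), rng.normal(1.0, 1, size=(6, 4))])
        groups = ["a"] * 6 + ["b"] * 6
        df = _mixed_frame(y, groups, 4)
        table = two_way_anova(df)
        aov = pg.mixed_anova(data=df, dv="value", within="level", subject="subject_id",
                             between="group")
        by_src = {r["Source"]: r for _, r in aov.iterrows()}
        assert table.effects["group"].f == pytest.approx(by_src["group"]["F"], rel=1e-6)
        assert table.effects["level"].f == pytest.approx(by_src["level"]["F"], rel=1e-6)
        assert table.effects["interaction"].f == pytest.approx(
            by_src["Interaction"]["F"], rel=1e-6
        )
        assert table.effects["group"].p == pytest.approx(by_src["group"]["p_unc"], rel=1e-6)

    def test_incomplete_within_rows_rejected(self):
        df = _mixed_frame(np.ones((4, 3)), ["a", "a", "b", "b"], 3)
        df = df.drop(index=df.index[-1])
        with pytest.raises(StatsInputError, match="s3"):
            two_way_anova(df)


class TestTukey:
    def test_equal_means_p_one(self):
        res = tukey_posthoc({"m1": 5.0, "m2": 5.0}, {"m1": 6, "m2": 6},
                            ms_error=2.0, df_error=10)
        assert res.comparisons[0][2] == pytest.approx(1.0)

    def test_large_shift_detected(self):
        rng = np.random.default_rng(0)
        groups = {"g1": rng.normal(0, 1, 10), "g2": rng.normal(0, 1, 10),
                  "g3": rng.normal(8, 1, 10)}  # 8 sd shift
        means = {k: float(np.mean(v)) for k, v in groups.items()}
        ns = {k: len(v) for k, v in groups.items()}
        pooled = np.concatenate([v - v.mean() for v in groups.values()])
        ms = float(pooled.var(ddof=3))
        res = tukey_posthoc(means, ns, ms, 27)
        ps = {c: p for c, _, p in res.comparisons}
        assert ps["g1 vs g2"] > 0.05
        assert ps["g1 vs g3"] < 0.05
        assert ps["g2 vs g3"] < 0.05

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(5)
        a, b, c = rng.normal(size=(3, 8))
        means = {"a": a.mean(), "b": b.mean(), "c": c.mean()}
        ns = {"a": 8, "b": 8, "c": 8}
        resid = np.concatenate([a - a.mean(), b - b.mean(), c - c.mean()])
        ms = float(resid.var(ddof=3))
        res = tukey_posthoc(means, ns, ms, 21)
        for (l1, l2) in (("a", "b"), ("a", "c"), ("b", "c")):
            t = (means[l1] - means[l2]) / math.sqrt(ms * (1 / 8 + 1 / 8))
            p_raw = 2 * sps.t.sf(abs(t), 21)
            p_adj = dict(((c_, p) for c_, _, p in res.comparisons))[f"{l1} vs {l2}"]
            assert p_adj >= p_raw - 1e-12


class TestSidak:
    def test_identity_m1(self):
        res = sidak_posthoc([0.05], m=1)
        assert res.comparisons[0][2] == pytest.approx(0.05)

    def test_closed_form_m2(self):
        res = sidak_posthoc([0.01], m=2)
        assert res.comparisons[0][2] == pytest.approx(1 - 0.99**2)

    def test_p_one_stays_one(self):
        res = sidak_posthoc([1.0], m=3)
        assert res.comparisons[0][2] == 1.0

    def test_invalid_m(self):
        with pytest.raises(StatsInputError):
            sidak_posthoc([0.5], m=0)


def _totals_frame(a_vals, b_vals, stat="distance_cm"):
    rows = []
    for i, v in enumerate(a_vals):
        rows.append({"subject_id": f"c{i}", "group": "control", "statistic": stat,
                     "value": v, "degenerate": False})
    for i, v in enumerate(b_vals):
        rows.append({"subject_id": f"t{i}", "group": "treated", "statistic": stat,
                     "value": v, "degenerate": False})
    return pd.DataFrame(rows)


class TestCompareCohort:
    def test_single_group_rejected(self):
        df = _totals_frame([1, 2, 3], [])
        with pytest.raises(StatsInputError):
            compare_cohort(df, design="totals")

    def test_type_one_error_calibration_small(self):
        rng = np.random.default_rng(7)
        rejections = 0
        n_rep = 300
        for _ in range(n_rep):
            df = _totals_frame(rng.normal(size=8), rng.normal(size=8))
            rep = compare_cohort(df, design="totals")
            rejections += rep["results"]["distance_cm"]["significant"]
        rate = rejections / n_rep
        assert 0.02 <= rate <= 0.09  # 0.05 plus Monte Carlo slack at n=300

    def test_shifted_groups_power(self):
        rng = np.random.default_rng(8)
        hits = 0
        for _ in range(50):
            df = _totals_frame(rng.normal(0, 0.1, 8), rng.normal(0.6, 0.1, 8))
            rep = compare_cohort(df, design="totals")
            hits += rep["results"]["distance_cm"]["significant"]
        assert hits >= 45

    def test_degenerate_exclusion_logged(self):
        df = _totals_frame([1.0, 2, 3], [4.0, 5, 6])
        df.loc[0, "degenerate"] = True
        rep = compare_cohort(df, design="totals")
        assert rep["exclusions"] == ["c0"]
        assert rep["results"]["distance_cm"]["group_ns"]["control"] == 2

    def test_minutes_design_runs_tukey(self):
        rng = np.random.default_rng(9)
        rows = []
        for g, shift in (("control", 0.0), ("treated", 0.0)):
            for s in range(6):
                base = rng.normal(10, 1)
                for minute in range(1, 6):
                    rows.append({"subject_id": f"{g}{s}", "group": g, "level": minute,
                                 "statistic": "distance_cm",
                                 "value": base - 1.5 * minute + rng.normal(0, 0.3)})
        rep = compare_cohort(pd.DataFrame(rows), design="minutes")
        entry = rep["results"]["distance_cm"]
        assert entry["anova"].effects["level"].p < 0.01  # strong time effect
        for g in ("control", "treated"):
            assert entry["posthoc"][g].comparisons[0][2] < 0.05

    def test_areas_design_runs_sidak(self):
        rng = np.random.default_rng(10)
        rows = []
        for g, soc_shift in (("control", -3.0), ("treated", 0.0)):
            for s in range(8):
                base = rng.normal(10, 0.5)
                rows.append({"subject_id": f"{g}{s}", "group": g, "level": "social",
                             "statistic": "mean_acc_cm_s2",
                             "value": base + soc_shift + rng.normal(0, 0.3)})
                rows.append({"subject_id": f"{g}{s}", "group": g, "level": "non_social",
                             "statistic": "mean_acc_cm_s2",
                             "value": base + rng.normal(0, 0.3)})
        rep = compare_cohort(pd.DataFrame(rows), design="areas")
        entry = rep["results"]["mean_acc_cm_s2"]
        assert entry["anova"].effects["interaction"].p < 0.05
        ps = {c: p for c, _, p in entry["posthoc"].comparisons}
        assert ps["control: non_social vs social"] < 0.05
        assert ps["treated: non_social vs social"] > 0.05
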