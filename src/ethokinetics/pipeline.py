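"""End-to-end cohort runs: per-subject kinematics, zones, and group stats.

A cohort manifest (CSV) lists one trajectory file per subject and test;
the pipeline summarizes each subject, bins by minute, computes zone
occupancy / social ratios where the arena provides them, excludes
degenerate (never-moving) subjects from the group statistics, and writes
tidy CSV outputs plus a provenance snapshot. Every number in the report is
regenerable from the config snapshot and the inputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .arenas import (
    ArenaSpec,
    SOCIAL_GROUPING,
    make_epm,
    make_open_field,
    make_three_chamber,
    per_zone_kinematics,
    social_ratio_report,
    zone_occupancy,
)
from .kinematics import (
    DEFAULT_EPSILON_CM,
    STATISTICS,
    Trajectory,
    bin_by_minute,
    summarize,
)
from .stats import StatsInputError, compare_cohort, comparison_table, tukey_posthoc

__all__ = ["RunConfig", "RunReport", "PipelineError", "run_pipeline", "habituation_profile",
           "default_arena"]


class PipelineError(ValueError):
    pass


MANIFEST_COLUMNS = ("subject_id", "group", "test", "path")


def default_arena(test: str) -> ArenaSpec:
    """Built-in arena for a manifest test label."""
    if test == "OFT":
        return make_open_field()
    if test in ("3C_habituation", "3C_social"):
        return make_three_chamber()
    if test == "EPM":
        return make_epm()
    raise PipelineError(f"no default arena for test {test!r}")


@dataclass(frozen=True)
class RunConfig:
    epsilon_cm: float = DEFAULT_EPSILON_CM
    bin_s: float = 60.0
    alpha: float = 0.05
    arenas: dict = field(default_factory=dict)  # test -> ArenaSpec (else default)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        arenas = {
            test: ArenaSpec.from_dict(spec) for test, spec in (d.get("arenas") or {}).items()
        }
        return cls(
            epsilon_cm=float(d.get("epsilon_cm", DEFAULT_EPSILON_CM)),
            bin_s=float(d.get("bin_s", 60.0)),
            alpha=float(d.get("alpha", 0.05)),
            arenas=arenas,
        )

    def snapshot(self) -> dict:
        return {
            "epsilon_cm": self.epsilon_cm,
            "bin_s": self.bin_s,
            "alpha": self.alpha,
            "arenas": {t: a.to_dict() for t, a in self.arenas.items()},
            "version": __version__,
        }


@dataclass
class RunReport:
    summaries: pd.DataFrame
    minutes: pd.DataFrame
    zones: pd.DataFrame
    ratios: pd.DataFrame
    stats: pd.DataFrame
    exclusions: list
    failures: list
    config_snapshot: dict

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.summaries.to_csv(out / "summaries.csv", index=False)
        self.minutes.to_csv(out / "minutes.csv", index=False)
        self.zones.to_csv(out / "zones.csv", index=False)
        self.ratios.to_csv(out / "ratios.csv", index=False)
        self.stats.to_csv(out / "stats.csv", index=False)
        prov = {
            "config": self.config_snapshot,
            "exclusions": self.exclusions,
            "failures": self.failures,
        }
        (out / "provenance.json").write_text(json.dumps(prov, indent=2, sort_keys=True))


def _load_manifest(manifest) -> pd.DataFrame:
    if isinstance(manifest, (str, Path)):
        df = pd.read_csv(manifest)
    else:
        df = manifest.copy()
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise PipelineError(f"manifest missing columns: {sorted(missing)}")
    dup = df.duplicated(subset=["subject_id", "test"])
    if dup.any():
        raise PipelineError("manifest has duplicate (subject_id, test) rows")
    return df


def run_pipeline(manifest, config: RunConfig | None = None,
                 trajectories: dict | None = None) -> RunReport:
    """Analyze every manifest row and compare groups per test.

    ``trajectories`` optionally maps (subject_id, test) to in-memory
    Trajectory objects, bypassing file loading (used by simulations and
    tests); otherwise each row's ``path`` is read as a trajectory CSV.
    Unreadable inputs are recorded as failures and the run continues; a
    group left empty after degenerate exclusions aborts the comparison for
    that test.
    """
    cfg = config or RunConfig()
    df = _load_manifest(manifest)
    sum_rows, min_rows, zone_rows, ratio_rows = [], [], [], []
    failures, exclusions = [], []
    per_test: dict[str, list] = {}

    for row in df.itertuples(index=False):
        key = (row.subject_id, row.test)
        try:
            if trajectories is not None and key in trajectories:
                traj = trajectories[key]
            else:
                traj = Trajectory.from_csv(row.path, subject_id=row.subject_id,
                                           group_label=row.group, test_stage=row.test)
            arena = cfg.arenas.get(row.test) or default_arena(row.test)
            summ = summarize(traj, cfg.epsilon_cm)
            rec = {"subject_id": row.subject_id, "group": row.group, "test": row.test}
            rec.update(summ.as_dict())
            sum_rows.append(rec)
            if summ.degenerate:
                exclusions.append({"subject_id": row.subject_id, "test": row.test,
                                   "reason": "degenerate: no moving steps"})
            for minute, ms in enumerate(bin_by_minute(traj, cfg.epsilon_cm, cfg.bin_s)):
                d = ms.as_dict()
                for stat in STATISTICS:
                    min_rows.append({"subject_id": row.subject_id, "group": row.group,
                                     "test": row.test, "minute": minute + 1,
                                     "statistic": stat, "value": d[stat]})
            occ = zone_occupancy(traj, arena)
            for z in arena.zones:
                zone_rows.append({"subject_id": row.subject_id, "group": row.group,
                                  "test": row.test, "zone": z.zone_id, "role": z.role,
                                  "seconds": occ.seconds[z.zone_id],
                                  "percent": occ.percent[z.zone_id]})
            if "chamber_social" in arena.roles() and not summ.degenerate:
                pz = per_zone_kinematics(traj, arena, cfg.epsilon_cm,
                                         role_grouping=SOCIAL_GROUPING)
                if "social" in pz and "non_social" in pz:
                    rep = social_ratio_report(pz)
                    for stat in STATISTICS:
                        ratio_rows.append({"subject_id": row.subject_id, "group": row.group,
                                           "test": row.test, "statistic": stat,
                                           "social": rep.social[stat],
                                           "non_social": rep.non_social[stat],
                                           "ratio": rep.ratio[stat]})
            per_test.setdefault(row.test, []).append((row.subject_id, row.group, summ))
        except (OSError, ValueError) as exc:
            failures.append({"subject_id": row.subject_id, "test": row.test,
                             "error": str(exc)})

    summaries = pd.DataFrame(sum_rows)
    stats_frames = []
    for test, entries in per_test.items():
        long_rows = []
        for sid, group, summ in entries:
            d = summ.as_dict()
            for stat in STATISTICS:
                long_rows.append({"subject_id": sid, "group": group, "statistic": stat,
                                  "value": d[stat], "degenerate": summ.degenerate})
        long_df = pd.DataFrame(long_rows)
        try:
            report = compare_cohort(long_df, design="totals")
        except StatsInputError as exc:
            failures.append({"subject_id": None, "test": test,
                             "error": f"group comparison skipped: {exc}"})
            continue
        tab = comparison_table(report)
        tab.insert(0, "test", test)
        stats_frames.append(tab)
    stats_df = pd.concat(stats_frames, ignore_index=True) if stats_frames else pd.DataFrame(
        columns=["test", "statistic", "effect", "stat_value", "p", "method"]
    )
    return RunReport(
        summaries=summaries,
        minutes=pd.DataFrame(min_rows),
        zones=pd.DataFrame(zone_rows),
        ratios=pd.DataFrame(ratio_rows),
        stats=stats_df,
        exclusions=exclusions,
        failures=failures,
        config_snapshot=cfg.snapshot(),
    )


def habituation_profile(minutes: pd.DataFrame, statistic: str = "distance_cm") -> dict:
    """Per-group minute curves (mean +/- SEM) with a first-vs-last contrast.

    ``minutes`` is the long-format per-minute table from the pipeline (or
    equivalent). The first-vs-last-minute contrast within each group uses
    the Tukey studentized range on the mixed-ANOVA within error.
    """
    from .stats import two_way_anova

    sub = minutes[minutes["statistic"] == statistic].dropna(subset=["value"])
    mins = sorted(sub["minute"].unique())
    if len(mins) < 2:
        raise PipelineError("need at least 2 minute bins")
    # only subjects with complete minute rows enter the ANOVA
    counts = sub.groupby("subject_id")["minute"].nunique()
    complete = counts[counts == len(mins)].index
    sub = sub[sub["subject_id"].isin(complete)]
    curves = (
        sub.groupby(["group", "minute"])["value"]
        .agg(mean="mean", sem=lambda v: v.std(ddof=1) / math.sqrt(len(v)), n="count")
        .reset_index()
    )
    table = two_way_anova(sub.rename(columns={"minute": "level"}), dv="value",
                          between="group", within="level", subject="subject_id",
                          design="mixed")
    contrasts = {}
    first, last = mins[0], mins[-1]
    for g in table.cell_means.index:
        means = {m: float(table.cell_means.loc[g, m]) for m in (first, last)}
        ns = {m: table.group_ns[g] for m in (first, last)}
        res = tukey_posthoc(means, ns, table.error_within_ms, table.error_within_df,
                            pairs=[(first, last)])
        contrasts[g] = res.comparisons[0]
    return {"statistic": statistic, "curves": curves, "anova": table,
            "first_vs_last": contrasts}
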