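"""One-command analysis: io -> microstructure -> timecourse -> stats.

``run_analysis`` reads a lick CSV (plus an optional cage-intake CSV),
computes per-train microstructure, binned time courses, cumulative
two-bottle paths and preference scores, then runs the group statistics:
split-plot ANOVAs (diet x solution on preference-day licks, licks per
cluster and cluster number; diet x day per conditioning solution), the
per-group paired t follow-ups, the between-group preference-score t test
and the intake t test.  Every number in the emitted results bundle is
produced by one operation in the library modules; this layer only routes
data.  Output files are written in deterministic order so re-runs are
byte-identical.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import microstructure as ms
from . import timecourse as tc
from .io import SessionRecord, CageIntakeRecord, read_lick_csv, per_rat_intake
from .simulate import CohortConfig, SimParams, simulate_experiment
from .stats import MixedAnova, TTestResult, t_paired, t_unpaired

logger = logging.getLogger("lickmicro")


@dataclass
class RunConfig:
    """Inputs and knobs for one analysis run."""

    input_csv: str | Path
    out_dir: str | Path
    intake_csv: str | Path | None = None
    threshold: float = 0.5
    bin_width: float = 60.0
    duration: float = 3600.0

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")


# ---------------------------------------------------------------------------
# tidy tables
# ---------------------------------------------------------------------------

def microstructure_table(sessions: Sequence[SessionRecord], threshold: float = 0.5) -> pd.DataFrame:
    """One row per (rat, session, bottle) with cluster metrics."""
    rows = []
    for s in sessions:
        for train in s.bottles:
            summ = ms.summarize(train, threshold=threshold)
            rows.append(dict(
                rat=s.rat_id, group=s.diet_group, session_type=s.session_type,
                day=s.day_index, bottle=train.bottle_label,
                solution=s.solution_map[train.bottle_label],
                total_licks=summ.total_licks, n_clusters=summ.n_clusters,
                mean_licks_per_cluster=summ.mean_licks_per_cluster,
                mean_within_cluster_ili=summ.mean_within_cluster_ili,
            ))
    return pd.DataFrame(rows).sort_values(
        ["rat", "session_type", "day", "bottle"]).reset_index(drop=True)


def timecourse_table(sessions: Sequence[SessionRecord], width: float = 60.0) -> pd.DataFrame:
    """One row per (rat, session, bottle, bin) with lick counts."""
    rows = []
    for s in sessions:
        for train in s.bottles:
            counts = tc.bin_licks(train, width=width, duration=s.duration)
            for k, c in enumerate(counts):
                rows.append(dict(
                    rat=s.rat_id, group=s.diet_group, session_type=s.session_type,
                    day=s.day_index, bottle=train.bottle_label,
                    solution=s.solution_map[train.bottle_label],
                    bin_start=k * width, count=int(c)))
    return pd.DataFrame(rows)


def cumulative_table(sessions: Sequence[SessionRecord]) -> pd.DataFrame:
    """Cumulative two-bottle paths for every preference session."""
    rows = []
    for s in sessions:
        if s.session_type != "preference":
            continue
        try:
            casein = s.train_for_solution("casein")
            malto = s.train_for_solution("maltodextrin")
        except KeyError:
            continue
        path = tc.cumulative_path(casein, malto)
        for i, (cc, cm) in enumerate(path.points):
            rows.append(dict(rat=s.rat_id, group=s.diet_group, day=s.day_index,
                             event_index=i, cum_casein=int(cc), cum_malto=int(cm)))
    return pd.DataFrame(rows, columns=["rat", "group", "day", "event_index",
                                       "cum_casein", "cum_malto"])


def preference_table(sessions: Sequence[SessionRecord], threshold: float = 0.5) -> pd.DataFrame:
    """Per-rat preference-day metrics for casein and maltodextrin."""
    rows = []
    for s in sessions:
        if s.session_type != "preference":
            continue
        try:
            casein = s.train_for_solution("casein")
            malto = s.train_for_solution("maltodextrin")
        except KeyError:
            logger.warning("preference session for rat %s lacks a casein/malto pair", s.rat_id)
            continue
        sc = ms.summarize(casein, threshold=threshold)
        sm = ms.summarize(malto, threshold=threshold)
        rows.append(dict(
            rat=s.rat_id, group=s.diet_group,
            casein_licks=sc.total_licks, malto_licks=sm.total_licks,
            casein_clusters=sc.n_clusters, malto_clusters=sm.n_clusters,
            casein_licks_per_cluster=sc.mean_licks_per_cluster,
            malto_licks_per_cluster=sm.mean_licks_per_cluster,
            preference=ms.preference_score(sc.total_licks, sm.total_licks)))
    return pd.DataFrame(rows, columns=[
        "rat", "group", "casein_licks", "malto_licks", "casein_clusters",
        "malto_clusters", "casein_licks_per_cluster",
        "malto_licks_per_cluster", "preference"])


# ---------------------------------------------------------------------------
# statistics stage
# ---------------------------------------------------------------------------

def _long_two_solution(pref: pd.DataFrame, casein_col: str, malto_col: str,
                       value: str) -> pd.DataFrame:
    parts = []
    for sol, col in (("casein", casein_col), ("maltodextrin", malto_col)):
        parts.append(pd.DataFrame(dict(
            rat=pref["rat"], group=pref["group"], solution=sol,
            **{value: pref[col]})))
    return pd.concat(parts, ignore_index=True)


def _anova_rows(tag: str, res) -> list[dict]:
    rows = []
    for key, eff in res.effects.items():
        rows.append(dict(
            analysis=tag, statistic=f"F[{eff.effect}]", kind="mixed-anova-" + key,
            value=eff.F, df1=eff.df,
            df2=next(s.df for s in res.strata if s.effect == eff.error_term),
            p=eff.p, significant=eff.significant))
    return rows


def _t_rows(tag: str, label: str, res: TTestResult) -> list[dict]:
    return [dict(analysis=tag, statistic=label, kind=res.kind, value=res.t,
                 df1=res.df, df2=math.nan, p=res.p, significant=res.significant)]


def preference_day_stats(pref: pd.DataFrame) -> list[dict]:
    """ANOVAs and follow-up t tests for the two-bottle preference day."""
    rows: list[dict] = []
    if pref.empty:
        return rows
    measures = [
        ("preference licks", "casein_licks", "malto_licks"),
        ("licks per cluster", "casein_licks_per_cluster", "malto_licks_per_cluster"),
        ("cluster number", "casein_clusters", "malto_clusters"),
    ]
    for tag, ccol, mcol in measures:
        sub = pref.dropna(subset=[ccol, mcol])
        dropped = len(pref) - len(sub)
        if dropped:
            logger.warning("%s: %d rat(s) dropped (undefined values)", tag, dropped)
        if sub["group"].nunique() >= 2 and (sub.groupby("group").size() >= 2).all():
            long = _long_two_solution(sub, ccol, mcol, "y")
            res = MixedAnova(long, dv="y", subject="rat", between="group",
                             within="solution").fit()
            rows += _anova_rows(tag, res)
        for group, g in sub.groupby("group"):
            if len(g) >= 2:
                res_t = t_paired(g[ccol], g[mcol])
                rows += _t_rows(tag, f"t[{group}: casein vs maltodextrin]", res_t)
    # between-group preference score (df surfaces any excluded rat)
    scored = pref.dropna(subset=["preference"])
    dropped = len(pref) - len(scored)
    if dropped:
        logger.warning("preference score: %d rat(s) excluded (no licks); df will reflect this",
                       dropped)
    by_group = {g: s["preference"].to_numpy() for g, s in scored.groupby("group")}
    if len(by_group) == 2 and all(v.size >= 2 for v in by_group.values()):
        groups = sorted(by_group)
        res_t = t_unpaired(by_group[groups[1]], by_group[groups[0]])
        rows += _t_rows("preference score", f"t[{groups[1]} vs {groups[0]}]", res_t)
    return rows


def conditioning_stats(micro: pd.DataFrame) -> list[dict]:
    """Diet x day (1st vs 2nd exposure) ANOVA per conditioning solution."""
    rows: list[dict] = []
    cond = micro[micro["session_type"] == "conditioning"]
    if cond.empty:
        return rows
    for solution, sub in cond.groupby("solution"):
        sub = sub.sort_values("day").copy()
        sub["exposure"] = sub.groupby("rat").cumcount() + 1
        sub = sub[sub["exposure"] <= 2]
        if sub["exposure"].nunique() < 2 or sub["group"].nunique() < 2:
            continue
        if not (sub.groupby("group")["rat"].nunique() >= 2).all():
            continue
        res = MixedAnova(sub, dv="total_licks", subject="rat", between="group",
                         within="exposure").fit()
        rows += _anova_rows(f"conditioning licks ({solution})", res)
    return rows


def intake_stats(records: Sequence[CageIntakeRecord]) -> list[dict]:
    """Unpaired t on per-rat daily intake, cage as the statistical unit."""
    by_group: dict[str, list[float]] = {}
    for r in records:
        by_group.setdefault(r.diet_group, []).append(per_rat_intake(r))
    if len(by_group) != 2 or any(len(v) < 2 for v in by_group.values()):
        return []
    res = t_unpaired(by_group["PR"], by_group["NR"])
    return _t_rows("cage intake (g/day/rat)", "t[PR vs NR]", res)


def read_intake_csv(path: str | Path) -> list[CageIntakeRecord]:
    df = pd.read_csv(path)
    return [CageIntakeRecord(str(r.cage), str(r.group), int(r.n_rats),
                             float(r.daily_intake_g))
            for r in df.itertuples()]


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_analysis(cfg: RunConfig) -> dict:
    """Execute the full pipeline and write the report bundle.

    Writes microstructure.csv, timecourse.csv, cumulative_paths.csv,
    preference.csv, stats.csv and results.json under ``cfg.out_dir``.
    Returns the results dictionary.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sessions = read_lick_csv(cfg.input_csv, duration=cfg.duration)
    if not sessions:
        raise ValueError("no sessions parsed from input")
    logger.info("read %d sessions (%d rats)", len(sessions),
                len({s.rat_id for s in sessions}))

    micro = microstructure_table(sessions, threshold=cfg.threshold)
    micro.to_csv(out / "microstructure.csv", index=False, float_format="%.6f",
                 lineterminator="\n")
    course = timecourse_table(sessions, width=cfg.bin_width)
    course.to_csv(out / "timecourse.csv", index=False, lineterminator="\n")

    pref = preference_table(sessions, threshold=cfg.threshold)
    stat_rows: list[dict] = []
    if pref.empty:
        logger.warning("no preference session found; skipping preference outputs")
    else:
        cumulative_table(sessions).to_csv(out / "cumulative_paths.csv",
                                          index=False, lineterminator="\n")
        pref.to_csv(out / "preference.csv", index=False, float_format="%.6f",
                    lineterminator="\n")
        stat_rows += preference_day_stats(pref)
    stat_rows += conditioning_stats(micro)

    if cfg.intake_csv is not None:
        stat_rows += intake_stats(read_intake_csv(cfg.intake_csv))

    stats_df = pd.DataFrame(stat_rows, columns=[
        "analysis", "statistic", "kind", "value", "df1", "df2", "p", "significant"])
    stats_df.to_csv(out / "stats.csv", index=False, float_format="%.6f",
                    lineterminator="\n")

    results = {
        "n_sessions": len(sessions),
        "n_rats": len({s.rat_id for s in sessions}),
        "threshold_s": cfg.threshold,
        "bin_width_s": cfg.bin_width,
        "statistics": stat_rows,
        "preference_by_group": (
            {} if pref.empty else
            {g: {"mean": float(s["preference"].mean()),
                 "n": int(s["preference"].notna().sum())}
             for g, s in pref.groupby("group")}),
    }
    (out / "results.json").write_text(
        json.dumps(_round_floats(results), indent=2, sort_keys=True) + "\n")
    return results


def _round_floats(obj, nd: int = 10):
    if isinstance(obj, float):
        return round(obj, nd) if math.isfinite(obj) else obj
    if isinstance(obj, dict):
        return {k: _round_floats(v, nd) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, nd) for v in obj]
    if isinstance(obj, (np.floating,)):
        return _round_floats(float(obj), nd)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


FIXTURE_PRESETS = {
    # n_rats per group, conditioning days, session duration (s)
    "tiny": dict(n_rats=2, n_conditioning_days=1, duration=600.0),
    "small": dict(n_rats=4, n_conditioning_days=2, duration=1200.0),
    "study": dict(n_rats=12, n_conditioning_days=4, duration=3600.0),
}


def make_fixtures(seed: int, preset: str, out_dir: str | Path) -> CohortConfig:
    """Write a small simulated cohort (CSV + manifest) for tests and demos."""
    if preset not in FIXTURE_PRESETS:
        raise ValueError(f"preset must be one of {sorted(FIXTURE_PRESETS)}")
    spec = FIXTURE_PRESETS[preset]
    cfg = CohortConfig(
        n_rats=spec["n_rats"], n_conditioning_days=spec["n_conditioning_days"],
        base_params=SimParams(duration=spec["duration"]), seed=seed)
    simulate_experiment(cfg).write(out_dir)
    return cfg
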