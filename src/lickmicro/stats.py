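"""Split-plot (two-way mixed) ANOVA and two-tailed t statistics.

The mixed design has one between-subjects factor (diet group) and one
within-subjects factor (solution or day), with each subject measured at
every within level.  The split-plot decomposition tests the between
effect against subjects-within-groups variance and the within and
interaction effects against the subject x within residual:

    SS_total      = SS_between-subjects + SS_within-subjects
    between:        SS_A + SS_subjects(A),      F_A  = MS_A  / MS_subj(A)
    within:         SS_B + SS_AB + SS_error,    F_B  = MS_B  / MS_err
                                                F_AB = MS_AB / MS_err

The decomposition is computed here from cell/subject means (no external
ANOVA routine); only the F and t distributions come from scipy.  On a
balanced design Type I/II/III sums of squares coincide; unbalanced data
fall back to a marginal-means (Type II style) decomposition with a logged
note.  All tests are two-tailed with the conventional alpha = 0.05.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger("lickmicro")

ALPHA = 0.05


# ---------------------------------------------------------------------------
# t statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TTestResult:
    """Two-tailed t statistic with its df and p-value.

    ``kind`` is ``paired`` or ``unpaired-pooled``.  A zero-variance
    comparison with unequal means reports ``t = +/-inf, p = 0`` and sets
    ``degenerate``; with equal means it reports ``t = 0, p = 1``.
    """

    t: float
    df: int
    p: float
    kind: str
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return self.p < ALPHA

    def __str__(self) -> str:
        return f"t({self.df}) = {self.t:.3f}, p = {self.p:.3g} [{self.kind}]"


def _finish_t(diff: float, se: float, df: int, kind: str) -> TTestResult:
    if se == 0.0:
        if diff == 0.0:
            return TTestResult(0.0, df, 1.0, kind, degenerate=True)
        return TTestResult(math.copysign(math.inf, diff), df, 0.0, kind, degenerate=True)
    t = diff / se
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TTestResult(float(t), df, p, kind)


def t_unpaired(x: Sequence[float], y: Sequence[float]) -> TTestResult:
    """Pooled-variance (Student) two-sample t test, two-tailed.

    df = n1 + n2 - 2.  Pooled rather than Welch variance: the classical
    Student statistic for two independent groups.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs >= 2 observations")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return _finish_t(float(x.mean() - y.mean()), se, df, "unpaired-pooled")


def t_paired(x: Sequence[float], y: Sequence[float]) -> TTestResult:
    """Paired t test: one-sample t on within-subject differences, df = n - 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("paired samples must have equal length")
    n = x.size
    if n < 2:
        raise ValueError("need >= 2 pairs")
    d = x - y
    se = float(d.std(ddof=1) / math.sqrt(n))
    return _finish_t(float(d.mean()), se, n - 1, "paired")


# ---------------------------------------------------------------------------
# Split-plot ANOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnovaEffect:
    """One line of the split-plot table."""

    effect: str
    ss: float
    df: int
    ms: float
    F: float
    p: float
    error_term: str

    @property
    def significant(self) -> bool:
        return not math.isnan(self.p) and self.p < ALPHA


class MixedAnovaResults:
    """Fitted split-plot decomposition.

    Carries the full stratum table (tested effects and their error terms),
    the cell means, and bookkeeping about dropped subjects.  ``effects``
    maps ``between`` / ``within`` / ``interaction`` to
    :class:`AnovaEffect`; ``to_frame()`` and ``summary()`` render the
    table.
    """

    def __init__(self, model: "MixedAnova", effects: dict[str, AnovaEffect],
                 strata: list[AnovaEffect], cell_means: pd.DataFrame,
                 n_subjects: int, n_dropped: int, zero_residual: bool) -> None:
        self.model = model
        self.effects = effects
        self.strata = strata
        self.cell_means = cell_means
        self.n_subjects = n_subjects
        self.n_dropped = n_dropped
        self.zero_residual = zero_residual

    def __getitem__(self, key: str) -> AnovaEffect:
        return self.effects[key]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            dict(effect=e.effect, SS=e.ss, df=e.df, MS=e.ms, F=e.F, p=e.p,
                 error_term=e.error_term)
            for e in self.strata
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        m = self.model
        lines = [
            "Split-plot (two-way mixed) ANOVA",
            f"  dv: {m.dv}   between: {m.between}   within: {m.within}",
            f"  subjects: {self.n_subjects}"
            + (f"   (dropped {self.n_dropped} incomplete)" if self.n_dropped else ""),
            "",
            f"{'effect':<28}{'SS':>12}{'df':>5}{'MS':>12}{'F':>10}{'p':>10}",
        ]
        for e in self.strata:
            fstr = f"{e.F:>10.3f}" if not math.isnan(e.F) else " " * 10
            pstr = f"{e.p:>10.4f}" if not math.isnan(e.p) else " " * 10
            lines.append(f"{e.effect:<28}{e.ss:>12.4f}{e.df:>5d}{e.ms:>12.4f}{fstr}{pstr}")
        if self.zero_residual:
            lines.append("  note: zero residual variance; infinite F reported with p = 0")
        return "\n".join(lines)


class MixedAnova:
    """Split-plot model: one between-subjects and one within-subjects factor.

    Parameters
    ----------
    data : long-form DataFrame with one row per (subject, within level).
    dv, subject, between, within : column names.

    Subjects missing any within level are listwise-dropped with a logged
    count, so reported df always reveal exclusions.  ``fit()`` returns a
    :class:`MixedAnovaResults`.
    """

    def __init__(self, data: pd.DataFrame, *, dv: str, subject: str,
                 between: str, within: str) -> None:
        for col in (dv, subject, between, within):
            if col not in data.columns:
                raise ValueError(f"column {col!r} not in data")
        self.data = data[[subject, between, within, dv]].copy()
        self.dv, self.subject, self.between, self.within = dv, subject, between, within

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, *, dv: str, subject: str,
                       between: str, within: str) -> "MixedAnova":
        return cls(data, dv=dv, subject=subject, between=between, within=within)

    # -- internals ---------------------------------------------------------

    def _wide(self) -> tuple[pd.DataFrame, pd.Series, int]:
        """Pivot to subjects x within levels; drop incomplete subjects."""
        d = self.data
        groups = d.groupby(self.subject)[self.between].nunique()
        if (groups > 1).any():
            bad = groups[groups > 1].index.tolist()
            raise ValueError(f"subject(s) {bad} appear in more than one between level")
        wide = d.pivot_table(index=self.subject, columns=self.within,
                             values=self.dv, aggfunc="mean")
        complete = wide.dropna()
        n_dropped = wide.shape[0] - complete.shape[0]
        if n_dropped:
            logger.warning("dropped %d subject(s) with incomplete within-level data", n_dropped)
        grp = d.drop_duplicates(self.subject).set_index(self.subject)[self.between]
        grp = grp.loc[complete.index]
        return complete, grp, n_dropped

    def fit(self) -> MixedAnovaResults:
        wide, grp, n_dropped = self._wide()
        y = wide.to_numpy(dtype=float)         # (N subjects, b within levels)
        N, b = y.shape
        if b < 2:
            raise ValueError("within factor needs >= 2 levels")
        levels_a = sorted(grp.unique())
        a = len(levels_a)
        sizes = np.array([(grp == g).sum() for g in levels_a])
        if (sizes < 2).any():
            raise ValueError("every between level needs >= 2 subjects")
        if a > 1 and len(set(sizes)) > 1:
            logger.info("unbalanced between-group sizes %s: marginal-means (Type II) decomposition",
                        dict(zip(levels_a, sizes.tolist())))

        grand = y.mean()
        subj_means = y.mean(axis=1)

        # between-subjects stratum (subject means, weighted by b levels)
        ss_subjects_total = b * float(((subj_means - grand) ** 2).sum())
        group_of = grp.to_numpy()
        ss_a = 0.0
        for g, n_g in zip(levels_a, sizes):
            gm = subj_means[group_of == g].mean()
            ss_a += b * n_g * (gm - grand) ** 2
        ss_subj_within = ss_subjects_total - ss_a
        df_a, df_subj = a - 1, N - a

        # within-subjects stratum on subject-centered data
        z = y - subj_means[:, None]
        rss0 = float((z ** 2).sum())
        level_means = z.mean(axis=0)                       # within main effect
        rss_b = float(((z - level_means[None, :]) ** 2).sum())
        cell = np.zeros((a, b))
        resid = z.copy()
        for i, g in enumerate(levels_a):
            mask = group_of == g
            cell[i] = z[mask].mean(axis=0)
            resid[mask] -= cell[i][None, :]
        rss_cell = float((resid ** 2).sum())
        ss_b = rss0 - rss_b
        ss_ab = rss_b - rss_cell
        ss_err = rss_cell
        df_b, df_ab = b - 1, (a - 1) * (b - 1)
        df_err = (N - a) * (b - 1)

        # numerical floor: tiny negative SS from cancellation -> 0
        ss_a, ss_b, ss_ab = (max(s, 0.0) for s in (ss_a, ss_b, ss_ab))

        def f_test(ss_eff: float, df_eff: int, ss_e: float, df_e: int) -> tuple[float, float, float, bool]:
            ms_eff = ss_eff / df_eff if df_eff else math.nan
            ms_e = ss_e / df_e if df_e else math.nan
            zero_resid = False
            if df_eff == 0:
                return math.nan, math.nan, ms_eff, zero_resid
            if ms_e == 0 or math.isnan(ms_e):
                if ss_eff <= 1e-12 * max(rss0, 1.0):
                    return 0.0, 1.0, ms_eff, False
                zero_resid = True
                return math.inf, 0.0, ms_eff, zero_resid
            F = ms_eff / ms_e
            return float(F), float(sps.f.sf(F, df_eff, df_e)), ms_eff, zero_resid

        zero_residual = False
        effects: dict[str, AnovaEffect] = {}
        strata: list[AnovaEffect] = []

        if a > 1:
            F, p, ms, zr = f_test(ss_a, df_a, ss_subj_within, df_subj)
            zero_residual |= zr
            eff = AnovaEffect(self.between, ss_a, df_a, ms, F, p, "subjects-within-groups")
            effects["between"] = eff
            strata.append(eff)
        strata.append(AnovaEffect("subjects-within-groups", ss_subj_within, df_subj,
                                  ss_subj_within / df_subj if df_subj else math.nan,
                                  math.nan, math.nan, ""))

        F, p, ms, zr = f_test(ss_b, df_b, ss_err, df_err)
        zero_residual |= zr
        eff = AnovaEffect(self.within, ss_b, df_b, ms, F, p, "subject-x-within residual")
        effects["within"] = eff
        strata.append(eff)

        if a > 1:
            F, p, ms, zr = f_test(ss_ab, df_ab, ss_err, df_err)
            zero_residual |= zr
            eff = AnovaEffect(f"{self.between} x {self.within}", ss_ab, df_ab, ms, F, p,
                              "subject-x-within residual")
            effects["interaction"] = eff
            strata.append(eff)
        strata.append(AnovaEffect("subject-x-within residual", ss_err, df_err,
                                  ss_err / df_err if df_err else math.nan,
                                  math.nan, math.nan, ""))

        cm = pd.DataFrame(
            [(g, lvl, y[group_of == g][:, k].mean())
             for g in levels_a for k, lvl in enumerate(wide.columns)],
            columns=[self.between, self.within, "mean"],
        )
        return MixedAnovaResults(self, effects, strata, cm, N, n_dropped, zero_residual)


def mixed_anova(data: pd.DataFrame, *, dv: str, subject: str, between: str,
                within: str) -> MixedAnovaResults:
    """Convenience wrapper: build and fit a :class:`MixedAnova` in one call."""
    return MixedAnova(data, dv=dv, subject=subject, between=between, within=within).fit()
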