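"""Monte-Carlo calibration of the statistics stage against the simulator.

Runs replicate simulated preference cohorts through the microstructure +
split-plot ANOVA pipeline and measures how often the diet x solution
interaction rejects.  Under the null (both groups indifferent, equal
palatability) the rejection rate estimates the type-I error and should
sit near alpha; under the study-sized effect (PR casein allocation 0.75,
palatability factor 1.4) it estimates power.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .microstructure import preference_score, summarize
from .simulate import CohortConfig, SimParams, simulate_preference_session
from .stats import ALPHA, MixedAnova

#: Session length (s) used for replicate calibration runs.  Type-I error
#: and power at these effect sizes are insensitive to session length, so
#: replicates use shorter sessions than the full hour-long design.
CALIBRATION_DURATION = 900.0


def simulate_preference_cohort(cfg: CohortConfig, seed: int) -> pd.DataFrame:
    """One preference session per rat; per-(rat, solution) metrics, long form."""
    rows = []
    for gi, group in enumerate(("NR", "PR")):
        for ri in range(cfg.n_rats):
            rng = np.random.Generator(np.random.PCG64(
                np.random.SeedSequence([seed, gi, ri])))
            s = simulate_preference_session(
                f"{group}{ri + 1:02d}", group,
                cfg.params_for(group, "casein"),
                cfg.params_for(group, "maltodextrin"),
                cfg.p_casein_for(group), rng)
            sc = summarize(s.train_for_solution("casein"))
            sm = summarize(s.train_for_solution("maltodextrin"))
            pref = preference_score(sc.total_licks, sm.total_licks)
            for sol, summ in (("casein", sc), ("maltodextrin", sm)):
                rows.append(dict(
                    rat=s.rat_id, group=group, solution=sol,
                    total_licks=summ.total_licks, n_clusters=summ.n_clusters,
                    licks_per_cluster=summ.mean_licks_per_cluster,
                    preference=pref))
    return pd.DataFrame(rows)


def null_cohort_config(n_rats: int = 12,
                       duration: float = CALIBRATION_DURATION) -> CohortConfig:
    """Effect-free design: both groups indifferent, equal palatability."""
    return CohortConfig(
        n_rats=n_rats, base_params=SimParams(duration=duration),
        pr_casein_size_factor=1.0, p_casein=(("NR", 0.5), ("PR", 0.5)),
        pr_day1_appetition_factor=1.0)


def effect_cohort_config(n_rats: int = 12,
                         duration: float = CALIBRATION_DURATION) -> CohortConfig:
    """Study-sized effect: PR casein allocation 0.75, palatability x1.4."""
    return CohortConfig(n_rats=n_rats, base_params=SimParams(duration=duration))


def interaction_rejection_rate(cfg: CohortConfig, n_reps: int, seed: int,
                               dv: str = "licks_per_cluster",
                               alpha: float = ALPHA) -> float:
    """Fraction of replicates whose diet x solution interaction has p < alpha."""
    rejections = 0
    for rep in range(n_reps):
        frame = simulate_preference_cohort(cfg, seed=seed * 100003 + rep)
        frame = frame.dropna(subset=[dv])
        res = MixedAnova(frame, dv=dv, subject="rat", between="group",
                         within="solution").fit()
        p = res["interaction"].p
        if not math.isnan(p) and p < alpha:
            rejections += 1
    return rejections / n_reps
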