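"""Synthetic clustered-licking generator with known ground truth.

The generator emulates hour-long lickometer sessions as an alternating
pause/cluster renewal process: draw a pause, then a cluster of licks whose
within-cluster interlick intervals (ILIs) sit in the rhythmic-licking band
(~6-7 Hz), and repeat until the session ends.  Cluster size encodes
palatability (its mean is the quantity the microstructure stage should
recover); the probability that a cluster initiates at the casein bottle
encodes preference.  Optional terms emulate satiation (pauses inflate
multiplicatively across clusters) and appetition (a step increase in
cluster size after a post-ingestive delay).

Within-cluster ILIs are truncated strictly below the 0.5 s cluster
threshold and pauses are floored strictly above it, so every generated
cluster is recoverable by segmentation *by construction* — a deliberate
idealization that makes ground truth exact.  ``ili_max`` can be raised
above the threshold for "leaky" robustness runs.

Randomness is hierarchical: the experiment seed spawns an independent
substream per rat (and per cage for intake), so adding a rat never
perturbs any other rat's data.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import (CageIntakeRecord, LickTrain, SessionRecord, write_session_csv)

CLUSTER_THRESHOLD = 0.5


class SimConfigError(ValueError):
    """Raised for generative parameters that break cluster recoverability."""


@dataclass(frozen=True)
class SimParams:
    """Generative parameters for one (rat, solution) lick train.

    Defaults describe a moderately palatable solution in a 1-h session:
    shifted-geometric cluster sizes (mean ``cluster_size_mean`` licks,
    support >= 1, memoryless run lengths), Normal within-cluster ILIs
    (mean 0.15 s ~ 6.7 Hz, SD 0.02 s, truncated to (0.05, 0.5]), and
    log-normal pauses (median 6 s) floored at 0.6 s.  ``satiety_decay``
    inflates each successive pause by a multiplicative factor;
    ``appetition_factor`` scales the cluster-size mean after
    ``appetition_onset`` seconds (post-ingestive positive feedback).
    """

    cluster_size_mean: float = 6.0
    cluster_size_law: str = "geometric"       # "geometric" | "nbinom"
    cluster_size_dispersion: float = 2.0      # nbinom shape (ignored for geometric)
    ili_mean: float = 0.15
    ili_sd: float = 0.02
    ili_min: float = 0.05
    ili_max: float = 0.5
    pause_median: float = 6.0
    pause_sigma: float = 0.6
    pause_min: float = 0.6
    satiety_decay: float = 0.0
    appetition_onset: float | None = None
    appetition_factor: float = 1.0
    duration: float = 3600.0

    def __post_init__(self) -> None:
        if self.cluster_size_mean < 1:
            raise SimConfigError("cluster_size_mean must be >= 1 (clusters have >= 1 lick)")
        for name in ("ili_mean", "ili_sd", "pause_median", "pause_sigma",
                     "pause_min", "duration"):
            if getattr(self, name) <= 0:
                raise SimConfigError(f"{name} must be positive")
        if self.satiety_decay < 0:
            raise SimConfigError("satiety_decay must be >= 0")
        if self.appetition_factor <= 0:
            raise SimConfigError("appetition_factor must be positive")
        if self.ili_mean >= CLUSTER_THRESHOLD:
            raise SimConfigError(
                "expected within-cluster ILI >= cluster threshold: clusters unrecoverable")
        if not (0 < self.ili_min < self.ili_max):
            raise SimConfigError("need 0 < ili_min < ili_max")

    def scaled(self, size_factor: float = 1.0, **overrides) -> "SimParams":
        """New params with the cluster-size mean scaled (palatability knob)."""
        return dataclasses.replace(
            self, cluster_size_mean=self.cluster_size_mean * size_factor, **overrides)


def _draw_cluster_size(params: SimParams, mu: float, rng: np.random.Generator) -> int:
    if mu <= 1.0:
        return 1
    if params.cluster_size_law == "geometric":
        return int(rng.geometric(1.0 / mu))
    if params.cluster_size_law == "nbinom":
        # shifted negative binomial: 1 + NB(r, p) with mean mu
        r = params.cluster_size_dispersion
        m = mu - 1.0
        p = r / (r + m)
        return 1 + int(rng.negative_binomial(r, p))
    raise SimConfigError(f"unknown cluster_size_law {params.cluster_size_law!r}")


def _draw_ilis(params: SimParams, k: int, rng: np.random.Generator) -> np.ndarray:
    ilis = rng.normal(params.ili_mean, params.ili_sd, size=k)
    return np.clip(ilis, params.ili_min, params.ili_max)


def _size_mean_at(params: SimParams, t: float) -> float:
    mu = params.cluster_size_mean
    if params.appetition_onset is not None and t >= params.appetition_onset:
        mu *= params.appetition_factor
    return mu


def simulate_train(params: SimParams, rng: np.random.Generator,
                   bottle_label: str = "spout") -> LickTrain:
    """Simulate one single-bottle session; reproducible given the rng state."""
    times: list[float] = []
    t = 0.0
    cluster_index = 0
    log_med = math.log(params.pause_median)
    while True:
        pause = max(rng.lognormal(log_med, params.pause_sigma), params.pause_min)
        pause *= (1.0 + params.satiety_decay) ** cluster_index
        start = t + pause
        if start > params.duration:
            break
        mu = _size_mean_at(params, start)
        k = _draw_cluster_size(params, mu, rng)
        ts = start + np.concatenate(([0.0], np.cumsum(_draw_ilis(params, k - 1, rng))))
        ts = ts[ts <= params.duration]
        times.extend(ts.tolist())
        t = float(ts[-1])
        cluster_index += 1
    return LickTrain(bottle_label, np.asarray(times))


def expected_preference(p_casein: float, mu_casein: float, mu_malto: float) -> float:
    """Closed-form long-run preference score.

    Clusters initiate at the casein bottle with probability p; lick totals
    are cluster counts times mean cluster size, so the score converges to
    p*mu_c / (p*mu_c + (1-p)*mu_m).
    """
    num = p_casein * mu_casein
    den = num + (1.0 - p_casein) * mu_malto
    if den == 0:
        return math.nan
    return num / den


def simulate_preference_session(
    rat_id: str, diet_group: str,
    params_casein: SimParams, params_malto: SimParams,
    p_casein: float, rng: np.random.Generator,
    day_index: int = 5,
    flavor_casein: str = "cherry", flavor_malto: str = "grape",
    casein_side: str = "left",
) -> SessionRecord:
    """Simulate a two-bottle preference session.

    A single pause/cluster process runs over the session; each cluster is
    allocated i.i.d. to the casein bottle with probability ``p_casein``
    and its size drawn from that bottle's palatability law.
    """
    if not 0.0 <= p_casein <= 1.0:
        raise SimConfigError("p_casein must lie in [0, 1]")
    duration = params_casein.duration
    casein_times: list[float] = []
    malto_times: list[float] = []
    t = 0.0
    cluster_index = 0
    log_med = math.log(params_casein.pause_median)
    while True:
        pause = max(rng.lognormal(log_med, params_casein.pause_sigma),
                    params_casein.pause_min)
        pause *= (1.0 + params_casein.satiety_decay) ** cluster_index
        start = t + pause
        if start > duration:
            break
        to_casein = rng.random() < p_casein
        par = params_casein if to_casein else params_malto
        k = _draw_cluster_size(par, _size_mean_at(par, start), rng)
        ts = start + np.concatenate(([0.0], np.cumsum(_draw_ilis(par, k - 1, rng))))
        ts = ts[ts <= duration]
        (casein_times if to_casein else malto_times).extend(ts.tolist())
        t = float(ts[-1])
        cluster_index += 1

    other_side = "right" if casein_side == "left" else "left"
    bottles = (
        LickTrain(casein_side, np.asarray(casein_times)),
        LickTrain(other_side, np.asarray(malto_times)),
    )
    return SessionRecord(
        rat_id=rat_id, diet_group=diet_group, session_type="preference",
        day_index=day_index, bottles=bottles,
        solution_map={casein_side: "casein", other_side: "maltodextrin"},
        flavor_map={casein_side: flavor_casein, other_side: flavor_malto},
        duration=duration,
    )


# ---------------------------------------------------------------------------
# Cohort-level simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortConfig:
    """Design of a simulated two-group flavor-nutrient conditioning study.

    Defaults encode the study conditions the analysis is meant to detect:
    12 rats per diet group, 4 alternating single-bottle conditioning days
    then a two-bottle preference test, protein-restricted (PR) rats with
    casein cluster sizes inflated by ``pr_casein_size_factor`` (elevated
    palatability) and casein allocation probability ``p_casein['PR']``
    (preference), non-restricted (NR) rats indifferent.  PR rats show a
    late-session appetition rise for casein on conditioning day 1.  Cage
    intake emulates group housing: 4 cages of 3 rats per group plus a
    pilot set of 4 cages of 2 rats per group, with PR hyperphagia as a
    multiplicative intake factor.
    """

    n_rats: int = 12
    base_params: SimParams = field(default_factory=SimParams)
    pr_casein_size_factor: float = 1.4
    p_casein: tuple[tuple[str, float], ...] = (("NR", 0.5), ("PR", 0.75))
    n_conditioning_days: int = 4
    pr_day1_appetition_factor: float = 1.4
    appetition_onset: float = 1200.0
    nr_intake_per_rat: float = 20.0
    intake_sd: float = 1.5
    pr_intake_factor: float = 1.15
    main_cages_per_group: int = 4
    main_cage_size: int = 3
    pilot_cages_per_group: int = 4
    pilot_cage_size: int = 2
    seed: int = 0

    def p_casein_for(self, group: str) -> float:
        return dict(self.p_casein)[group]

    def params_for(self, group: str, solution: str) -> SimParams:
        factor = self.pr_casein_size_factor if (group == "PR" and solution == "casein") else 1.0
        return self.base_params.scaled(factor)


@dataclass
class ExperimentData:
    """Output bundle of :func:`simulate_experiment`."""

    sessions: list[SessionRecord]
    cage_intake: list[CageIntakeRecord]
    manifest: dict

    def write(self, out_dir: str | Path) -> None:
        """Write canonical CSVs plus a ground-truth manifest JSON."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_session_csv(self.sessions, out / "licks.csv")
        rows = ["cage,group,n_rats,daily_intake_g"]
        for c in self.cage_intake:
            rows.append(f"{c.cage_id},{c.diet_group},{c.n_rats},{c.daily_intake:.4f}")
        (out / "intake.csv").write_text("\n".join(rows) + "\n")
        (out / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True) + "\n")


def _rat_rng(seed: int, group_idx: int, rat_idx: int) -> np.random.Generator:
    # fixed spawn key per rat: adding rats never perturbs existing streams
    return np.random.Generator(np.random.PCG64(
        np.random.SeedSequence([seed, group_idx, rat_idx])))


def simulate_experiment(cfg: CohortConfig) -> ExperimentData:
    """Simulate the full design: conditioning block, preference test, intake.

    Conditioning solutions alternate over ``n_conditioning_days`` with
    order and flavor assignment counterbalanced across rats.  Returns all
    sessions, the cage intake table, and a manifest holding every
    generative parameter plus closed-form expectations.
    """
    sessions: list[SessionRecord] = []
    groups = ("NR", "PR")
    for gi, group in enumerate(groups):
        for ri in range(cfg.n_rats):
            rng = _rat_rng(cfg.seed, gi, ri)
            rat_id = f"{group}{ri + 1:02d}"
            casein_first = ri % 2 == 0
            casein_flavor = "cherry" if ri % 4 < 2 else "grape"
            malto_flavor = "grape" if casein_flavor == "cherry" else "cherry"
            casein_side = "left" if casein_first else "right"
            for day in range(1, cfg.n_conditioning_days + 1):
                solution = ("casein" if (day % 2 == 1) == casein_first
                            else "maltodextrin")
                params = cfg.params_for(group, solution)
                if (group == "PR" and solution == "casein"
                        and day <= 2 and cfg.pr_day1_appetition_factor != 1.0):
                    # appetition on the first casein exposure (day 1 or 2
                    # depending on counterbalancing)
                    first_casein_day = 1 if casein_first else 2
                    if day == first_casein_day:
                        params = dataclasses.replace(
                            params,
                            appetition_onset=cfg.appetition_onset,
                            appetition_factor=cfg.pr_day1_appetition_factor)
                train = simulate_train(params, rng, bottle_label="left")
                sessions.append(SessionRecord(
                    rat_id=rat_id, diet_group=group, session_type="conditioning",
                    day_index=day, bottles=(train,),
                    solution_map={"left": solution},
                    flavor_map={"left": casein_flavor if solution == "casein" else malto_flavor},
                    duration=cfg.base_params.duration,
                ))
            sessions.append(simulate_preference_session(
                rat_id, group,
                cfg.params_for(group, "casein"),
                cfg.params_for(group, "maltodextrin"),
                cfg.p_casein_for(group), rng,
                day_index=cfg.n_conditioning_days + 1,
                flavor_casein=casein_flavor, flavor_malto=malto_flavor,
                casein_side=casein_side,
            ))

    cage_intake: list[CageIntakeRecord] = []
    cage_idx = 0
    for cohort, n_cages, cage_size in (
            ("main", cfg.main_cages_per_group, cfg.main_cage_size),
            ("pilot", cfg.pilot_cages_per_group, cfg.pilot_cage_size)):
        for group in groups:
            mean = cfg.nr_intake_per_rat * (cfg.pr_intake_factor if group == "PR" else 1.0)
            for _ in range(n_cages):
                rng = np.random.Generator(np.random.PCG64(
                    np.random.SeedSequence([cfg.seed, 97, cage_idx])))
                per_rat = max(rng.normal(mean, cfg.intake_sd), 0.0)
                cage_intake.append(CageIntakeRecord(
                    cage_id=f"{cohort}_{group}_c{cage_idx + 1}", diet_group=group,
                    n_rats=cage_size, daily_intake=per_rat * cage_size))
                cage_idx += 1

    mu = cfg.base_params.cluster_size_mean
    manifest = {
        "config": _jsonable(dataclasses.asdict(cfg)),
        "expected": {
            "preference_NR": expected_preference(cfg.p_casein_for("NR"), mu, mu),
            "preference_PR": expected_preference(
                cfg.p_casein_for("PR"), mu * cfg.pr_casein_size_factor, mu),
            "licks_per_cluster": {
                "NR_casein": mu, "NR_maltodextrin": mu,
                "PR_casein": mu * cfg.pr_casein_size_factor, "PR_maltodextrin": mu,
            },
        },
    }
    return ExperimentData(sessions=sessions, cage_intake=cage_intake, manifest=manifest)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
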