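"""Generational loop, replicate runs, and the four sensitivity experiments.

One generational step composes, in order: draw the generation's optimum,
assign expected RS from fitness weights, size the next generation from
female expected RS, build pair weights (with the temporal-overlap gate in
assortative mode), assign a dam and sire to every offspring, draw offspring
traits around mid-parent values, and summarize the breeding cohort (whose
RS_obs defines its Ne).

An iteration initializes founders and steps through the configured number of
generations; reproductive failure or an empty cohort is a terminal state —
remaining generations are recorded as census zero so replicate means include
collapsed populations.  The functional-extinction flag (Nc below the
threshold) does not stop a run.

The four experiments sweep, around a common base (Nc0 = 500, mu = (10, 5),
var_rls = 20, var_theta_rls = 1; intermediate defaults var_return_day = 20,
rho = -0.3, var_theta_return_day = 20, omega = 2, assortative mating):

1. var_return_day in {10, 20, 30} under assortative and random mating;
2. rho in {-0.6, -0.3, 0};
3. var_theta_return_day in {10, 20, 30};
4. omega in {1, 2, 3}.

Replicate seeds derive from the master seed via
``numpy.random.SeedSequence(master, spawn_key=(level_index, iteration_index))``,
so any level or iteration can be re-run in isolation and reruns are
byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .config import Cohort, CovarianceSet, SimulationConfig, build_covariances
from .fitness import assign_expected_rs, draw_optima
from .inheritance import make_offspring_cohort
from .mating import assign_parents, pair_weights, recruit_count
from .summaries import (CohortSummary, aggregate_iterations,
                        summaries_to_frame, summarize_cohort)

logger = logging.getLogger("phenomate")

SeedLike = Union[int, np.random.SeedSequence, None]


def run_generation(cohort: Cohort, cfg: SimulationConfig, covs: CovarianceSet,
                   rng, id_start: int = 0
                   ) -> Tuple[Cohort, CohortSummary]:
    """Advance one generation; returns (next cohort, summary of this cohort).

    The summary describes the *breeding* cohort, including the Ne implied by
    its realized RS_obs.  An empty next cohort (reproductive failure or no
    recruits) is a normal terminal state, not an error.
    """
    optimum = draw_optima(cfg, rng)
    cohort.theta = optimum.vector
    assign_expected_rs(cohort, cfg, covs.Omega, rng, Omega_inv=covs.Omega_inv)
    n_next = recruit_count(cohort)
    weights = pair_weights(cohort, cfg.mating_mode)
    assignments = assign_parents(cohort, n_next, weights, rng)
    nxt = make_offspring_cohort(cohort, assignments, cfg, rng, P=covs.P,
                                id_start=id_start)
    summary = summarize_cohort(cohort, cfg.extinction_threshold)
    return nxt, summary


def run_iteration(cfg: SimulationConfig, seed: SeedLike,
                  collect_pedigree: bool = False
                  ) -> Union[List[CohortSummary],
                             Tuple[List[CohortSummary], pd.DataFrame]]:
    """Run founders plus ``cfg.generations`` generational steps.

    Returns one :class:`CohortSummary` per generation 0..generations.  The
    final cohort also goes through a reproduction step (its offspring are
    discarded) so that its Ne is defined from realized RS_obs.  Deterministic
    given the seed.  With ``collect_pedigree`` the full pedigree (animal,
    dam, sire, sex, traits, RS) is returned as a DataFrame as well.
    """
    rng = np.random.default_rng(seed)
    covs = build_covariances(cfg)
    from .initialization import init_founders

    cohort = init_founders(cfg, rng, P=covs.P)
    next_id = cohort.size
    summaries: List[CohortSummary] = []
    cohorts: List[Cohort] = []
    for gen in range(cfg.generations + 1):
        if cohort.size == 0:
            summaries.append(summarize_cohort(cohort, cfg.extinction_threshold))
            cohorts.append(cohort)
            cohort = Cohort.empty(gen + 1)
            continue
        nxt, summary = run_generation(cohort, cfg, covs, rng, id_start=next_id)
        summaries.append(summary)
        cohorts.append(cohort)
        next_id += nxt.size
        cohort = nxt
    if collect_pedigree:
        return summaries, _pedigree_frame(cohorts)
    return summaries


def _pedigree_frame(cohorts: Sequence[Cohort]) -> pd.DataFrame:
    frames = []
    for c in cohorts:
        if c.size == 0:
            continue
        frames.append(pd.DataFrame({
            "generation": c.generation,
            "animal": c.ids,
            "dam": c.dam_id,
            "sire": c.sire_id,
            "sex": np.where(c.is_female, "female", "male"),
            "return_day": c.return_day,
            "rls": c.rls,
            "rs_exp": c.rs_exp if c.rs_exp is not None else -1,
            "rs_obs": c.rs_obs if c.rs_obs is not None else -1,
        }))
    if not frames:
        return pd.DataFrame(columns=["generation", "animal", "dam", "sire",
                                     "sex", "return_day", "rls", "rs_exp",
                                     "rs_obs"])
    return pd.concat(frames, ignore_index=True)


def child_seed(master_seed: Optional[int], level_index: int,
               iteration_index: int) -> np.random.SeedSequence:
    """Stable per-replicate seed: SeedSequence(master, spawn_key=(level, iter))."""
    return np.random.SeedSequence(master_seed,
                                  spawn_key=(level_index, iteration_index))


def run_replicates(cfg: SimulationConfig, master_seed: Optional[int] = None,
                   iterations: Optional[int] = None, level_index: int = 0
                   ) -> pd.DataFrame:
    """Run replicate iterations of one configuration; long summary DataFrame."""
    if master_seed is None:
        master_seed = cfg.seed
    n_iter = cfg.iterations if iterations is None else iterations
    streams = [run_iteration(cfg, child_seed(master_seed, level_index, it))
               for it in range(n_iter)]
    return summaries_to_frame(streams)


@dataclass(frozen=True)
class ExperimentSpec:
    """One published sensitivity experiment: a base config plus named levels.

    Each level is a dict of config overrides; exactly one model parameter is
    probed per experiment (experiment 1 additionally crosses the swept
    variance with the mating mode).
    """

    name: str
    base: SimulationConfig
    levels: Tuple[Tuple[str, dict], ...]  # (label, overrides)
    master_seed: Optional[int] = None

    def configs(self) -> List[Tuple[str, SimulationConfig]]:
        return [(label, self.base.replace(**ov)) for label, ov in self.levels]


#: parameters held constant across all four experiments
BASE_PARAMS: Dict[str, float] = dict(
    nc_initial=500, mu_return_day=10.0, mu_rls=5.0,
    var_return_day=20.0, var_rls=20.0, rho=-0.3, omega_scalar=2.0,
    var_theta_return_day=20.0, var_theta_rls=1.0,
    generations=10, iterations=100, mating_mode="assortative",
)


def base_config(**overrides) -> SimulationConfig:
    """The common experiment base configuration, with optional overrides."""
    params = dict(BASE_PARAMS)
    params.update(overrides)
    return SimulationConfig(**params)


def experiment_spec(name: str, master_seed: Optional[int] = None,
                    **base_overrides) -> ExperimentSpec:
    """Build one of the four published experiment presets (exp1..exp4)."""
    base = base_config(**base_overrides)
    if name == "exp1":
        # the published random-mating control assigns dam-sire-offspring
        # triads uniformly (all pair weights 1), hence random_uniform
        levels = tuple(
            (f"var_rd={v}_{label}",
             {"var_return_day": float(v), "mating_mode": mode})
            for label, mode in (("assortative", "assortative"),
                                ("random", "random_uniform"))
            for v in (10, 20, 30))
    elif name == "exp2":
        levels = tuple((f"rho={r}", {"rho": r}) for r in (-0.6, -0.3, 0.0))
    elif name == "exp3":
        levels = tuple((f"var_theta_rd={v}", {"var_theta_return_day": float(v)})
                       for v in (10, 20, 30))
    elif name == "exp4":
        levels = tuple((f"omega={w}", {"omega_scalar": float(w)})
                       for w in (1.0, 2.0, 3.0))
    else:
        raise ValueError(f"unknown experiment {name!r}; expected exp1..exp4")
    return ExperimentSpec(name=name, base=base, levels=levels,
                          master_seed=master_seed)


EXPERIMENT_NAMES = ("exp1", "exp2", "exp3", "exp4")


def run_experiment(spec: ExperimentSpec
                   ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Run all levels of an experiment; returns (raw, aggregated) tables.

    Raw: one row per (level, iteration, generation).  Aggregated: replicate
    means with 95% CIs per (level, generation).
    """
    raw_frames = []
    agg_frames = []
    for li, (label, cfg) in enumerate(spec.configs()):
        logger.info("experiment %s: level %s (%d iterations)",
                    spec.name, label, cfg.iterations)
        raw = run_replicates(cfg, spec.master_seed, level_index=li)
        raw.insert(0, "level", label)
        agg = aggregate_iterations(raw.drop(columns="level"))
        agg.insert(0, "level", label)
        raw_frames.append(raw)
        agg_frames.append(agg)
    return (pd.concat(raw_frames, ignore_index=True),
            pd.concat(agg_frames, ignore_index=True))
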