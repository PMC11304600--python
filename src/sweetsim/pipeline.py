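"""Year-by-year execution of the five breeding-program scenarios.

Scenarios
---------
Conv   conventional phenotypic program: cross, self with nursery truncation,
       three testcross rounds (TC1-TC3) against elite private testers,
       release of the top inbreds. One recurrent-selection cycle spans
       5 years.
GSTC   Conv calendar with marker-based selection at the nursery steps; the
       model trains on testcross GCA of the program's own parents
       (150/100/15 records per year at 50 crosses) in a 4-year window.
GSF1   as GSTC but trained on yearly trials of 800 F1 families phenotyped in
       the target environment.
DH     doubled haploids replace the selfing ladder: each year's F1s are
       turned into DH lines that enter the testcross rounds directly;
       release cycle shrinks to 4 years; parents recycle from TC2 ranking.
DHGS   DH plus genomic selection: crossing-block parents are picked among
       the newest DH lines by GEBV (early recycling), training as GSTC but
       with the larger DH testcross populations (800/200/100).

All stages run every year (overlapping cohorts), which is what makes the
published per-year plot/cost schedules annual figures; line releases and
private-program tester turnover are booked once per completed cycle.
A parallel private program (conventional, four-fold stage sizes, per-se
phenotypic truncation) supplies the five elite testers.

Every scenario starts from the same 15-year conventional burn-in: for a
fixed seed the post-burn-in state is bit-identical across scenarios, so
paired comparisons share founders, trait, environments and starting
population.
"""

from __future__ import annotations

import copy
import dataclasses
import math
from typing import Optional

import numpy as np
import pandas as pd

from . import economics
from .genome import (PRIVATE, PUBLIC, GenomeSpec, Population, cross_pairs,
                     make_dh_each, self_each, simulate_founders)
from .prediction import RRBLUP, TrainingSet, estimate_gca, fit_rrblup, \
    predict_gebv
from .trait import (OFFSEASON, TARGET, EnvironmentTable, TraitArchitecture,
                    build_trait, genetic_value, phenotype)

__all__ = [
    "SCENARIOS",
    "ScenarioConfig",
    "Cohort",
    "ProgramState",
    "RunResult",
    "select_parents",
    "run_burnin",
    "advance_year",
    "run_private_program",
    "evaluate",
    "run_scenario",
    "run_scenarios_shared",
]

SCENARIOS = ("Conv", "GSTC", "GSF1", "DH", "DHGS")
GS_SCENARIOS = ("GSTC", "GSF1", "DHGS")
DH_SCENARIOS = ("DH", "DHGS")
RATIOS = {"3:1": 0.75, "1:1": 0.5, "1:3": 0.25, "0:1": 0.0}


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclasses.dataclass
class ScenarioConfig:
    """Full description of one pipeline variant.

    Stage sizes are stated at the 50-cross program size and scale linearly
    with ``n_crosses / 50`` (the published 200-cross program is exactly four
    times as large at every stage).
    """

    scenario: str = "Conv"
    n_crosses: int = 50
    substitution_ratio: str = "1:3"        # old:new parents in the block
    burnin_substitution_ratio: str = "1:1"  # fixed during the shared burn-in
    heritability: str = "low"              # high -> sigma2res 60, low -> 240
    ge_multiplier: float = 10.0            # 0 or 10 x additive variance
    burn_in_years: int = 15
    eval_years: int = 20
    tc_testers: tuple = (1, 3, 5)
    tc_trials: tuple = (2, 5, 20)
    conv_tc_parents: tuple = (150, 100, 15)
    dh_tc_parents: tuple = (800, 200, 100)
    f1_training_size: int = 800
    new_parent_pool_size: int = 50
    releases_per_cycle: int = 2
    private_scale: int = 4
    private_releases: int = 5
    dh_lines_total: int = 800
    progeny_per_self: int = 10
    training_window_years: int = 4
    # founder genome
    n_founders: int = 100
    split_generations: int = 30
    founder_method: str = "coalescent"
    n_chromosomes: int = 10
    morgans_per_chr: float = 2.0
    qtn_per_chr: int = 300
    snp_per_chr: int = 3000

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; "
                             f"choose from {SCENARIOS}")
        if self.substitution_ratio not in RATIOS:
            raise ValueError(f"substitution_ratio must be one of "
                             f"{sorted(RATIOS)}")
        if self.burnin_substitution_ratio not in RATIOS:
            raise ValueError(f"burnin_substitution_ratio must be one of "
                             f"{sorted(RATIOS)}")
        if self.heritability not in ("high", "low"):
            raise ValueError("heritability must be 'high' or 'low'")
        if self.n_crosses < 2:
            raise ValueError("n_crosses must be >= 2")
        if any(a < b for a, b in zip(self.tc_parents("conv"),
                                     self.tc_parents("conv")[1:])):
            raise ValueError("testcross stage sizes must be non-increasing")

    # -- derived ------------------------------------------------------------

    @property
    def residual_var(self) -> float:
        return 60.0 if self.heritability == "high" else 240.0

    @property
    def old_fraction(self) -> float:
        return RATIOS[self.substitution_ratio]

    @property
    def burnin_old_fraction(self) -> float:
        return RATIOS[self.burnin_substitution_ratio]

    @property
    def cycle_years(self) -> int:
        return 4 if self.scenario in DH_SCENARIOS else 5

    @property
    def uses_gs(self) -> bool:
        return self.scenario in GS_SCENARIOS

    @property
    def size_factor(self) -> float:
        return self.n_crosses / 50.0

    def scaled(self, base: int) -> int:
        return max(int(round(base * self.size_factor)), 1)

    def tc_parents(self, pipeline: str) -> tuple:
        base = self.dh_tc_parents if pipeline == "dh" else self.conv_tc_parents
        k = self.private_scale if pipeline == "private" else 1
        return tuple(self.scaled(b) * k for b in base)

    def nursery_keep(self, pipeline: str) -> int:
        k = self.private_scale if pipeline == "private" else 1
        return self.scaled(self.conv_tc_parents[0]) * k

    def genome_spec_kwargs(self) -> dict:
        return dict(n_chromosomes=self.n_chromosomes,
                    morgans_per_chr=self.morgans_per_chr,
                    qtn_per_chr=self.qtn_per_chr,
                    snp_per_chr=self.snp_per_chr)

    def shared_key(self) -> tuple:
        """Fields that must agree for scenarios to share one burn-in."""
        return (self.n_crosses, self.heritability, self.ge_multiplier,
                self.burn_in_years, self.n_founders, self.split_generations,
                self.founder_method, self.n_chromosomes, self.morgans_per_chr,
                self.qtn_per_chr, self.snp_per_chr, self.progeny_per_self,
                self.tc_testers, self.tc_trials, self.conv_tc_parents,
                self.new_parent_pool_size, self.private_scale,
                self.private_releases, self.burnin_substitution_ratio)


# --------------------------------------------------------------------------
# state
# --------------------------------------------------------------------------

@dataclasses.dataclass
class Cohort:
    uid: int
    pop: Population
    pipeline: str      # "conv" | "dh" | "private"
    age: int = 0
    scores: Optional[np.ndarray] = None
    done: bool = False


@dataclasses.dataclass
class RunResult:
    scenario: str
    seed: int
    metrics: pd.DataFrame
    released: list
    config: ScenarioConfig


class ProgramState:
    """Evolving cohorts, crossing blocks, testers, training data, metrics."""

    def __init__(self, config: ScenarioConfig, genome: GenomeSpec,
                 trait: TraitArchitecture, founders: Population,
                 rng_burn, rng_eval, env: EnvironmentTable):
        self.config = config
        self.genome = genome
        self.trait = trait
        self.founders = founders
        self.rng = rng_burn
        self._rng_eval = rng_eval
        self.env = env
        self.year = 0
        self.next_id = int(founders.ids.max()) + 1
        self.cohorts: list[Cohort] = []
        self._next_uid = 0
        self.training = TrainingSet(config.training_window_years)
        self.model: Optional[RRBLUP] = None
        self.released: list[dict] = []
        self.n_released_eval = 0
        self.metrics: list[dict] = []
        self.phenotype_log: list[dict] = []

        rng = self.rng
        pub = np.flatnonzero(founders.pool == PUBLIC)
        prv = np.flatnonzero(founders.pool == PRIVATE)
        self.crossing_block = self._sample_block(founders, pub,
                                                 config.n_crosses, rng)
        self.block_scores = np.zeros(self.crossing_block.n)
        n_private = config.private_scale * config.n_crosses
        self.private_block = self._sample_block(founders, prv, n_private, rng)
        self.private_scores = np.zeros(self.private_block.n)
        t_rows = rng.choice(prv, size=config.private_releases, replace=False)
        self.tester_set = founders.subset(np.sort(t_rows))
        # per-year scratch
        self._tc1_snapshot = None
        self._tc2_snapshot = None
        self._tc3_hybrid_mean = math.nan
        self._release_pool = None
        self._private_candidates = None
        self._private_finished = None

    # -- helpers ------------------------------------------------------------

    def take_ids(self, k: int) -> int:
        start = self.next_id
        self.next_id += k
        return start

    def take_uid(self) -> int:
        self._next_uid += 1
        return self._next_uid

    def _sample_block(self, founders, rows, k, rng):
        replace = k > rows.size
        sel = np.sort(rng.choice(rows, size=k, replace=replace))
        ids = self.take_ids(k) + np.arange(k, dtype=np.int64)
        return Population(founders.genome, founders.haplo[sel], ids,
                          founders.mother[sel], founders.father[sel],
                          founders.cohort_tag, founders.birth_year,
                          founders.pool[sel])

    @property
    def in_eval(self) -> bool:
        return self.year > self.config.burn_in_years

    @property
    def eval_year(self) -> int:
        return max(self.year - self.config.burn_in_years, 0)

    @property
    def effective_scenario(self) -> str:
        """Burn-in always runs the conventional program."""
        return self.config.scenario if self.in_eval else "Conv"

    def log_phenotypes(self, cohort_uid, pipeline, stage, n):
        self.phenotype_log.append(dict(year=self.year, cohort=cohort_uid,
                                       pipeline=pipeline, stage=stage, n=n))

    def copy(self) -> "ProgramState":
        return copy.deepcopy(self)


# --------------------------------------------------------------------------
# ranking / parental substitution
# --------------------------------------------------------------------------

def _top_rows(scores, ids, k):
    """Row indices of the k best scores; ties broken by ascending id."""
    order = np.lexsort((np.asarray(ids), -np.asarray(scores, dtype=float)))
    return order[:k]


def select_parents(old_parents: Population, old_scores,
                   candidates: Population, cand_scores,
                   ratio, n_slots: int):
    """Compose a crossing block from old parents and new candidates.

    ``ratio`` is an "old:new" string (3:1, 1:1, 1:3, 0:1) or the old
    fraction directly. n_old = floor(n_slots * old_fraction) top-ranked old
    parents are retained; the rest of the block is filled with top-ranked
    new candidates. Deterministic id tie-break throughout.
    """
    frac = RATIOS[ratio] if isinstance(ratio, str) else float(ratio)
    if not 0.0 <= frac <= 1.0:
        raise ValueError("old fraction must be in [0, 1]")
    n_old = int(math.floor(n_slots * frac))
    n_new = n_slots - n_old
    if old_parents.n < n_old:
        raise RuntimeError(f"only {old_parents.n} old parents for "
                           f"{n_old} slots")
    if candidates.n < n_new:
        raise RuntimeError(f"only {candidates.n} candidates for "
                           f"{n_new} slots")
    parts, scores = [], []
    if n_old:
        rows = _top_rows(old_scores, old_parents.ids, n_old)
        parts.append(old_parents.subset(rows))
        scores.append(np.asarray(old_scores, dtype=float)[rows])
    rows = _top_rows(cand_scores, candidates.ids, n_new)
    parts.append(candidates.subset(rows))
    scores.append(np.asarray(cand_scores, dtype=float)[rows])
    block = parts[0] if len(parts) == 1 else Population.concat(parts)
    return block, np.concatenate(scores)


# --------------------------------------------------------------------------
# stage handlers
# --------------------------------------------------------------------------

def _check_cohort(state, co, stage):
    if co.pop.n == 0:
        raise RuntimeError(
            f"empty cohort at stage {stage} (pipeline {co.pipeline}) "
            f"in year {state.year}")


def _stage_nursery(state: ProgramState, co: Cohort):
    """Self F1s into a nursery of progeny rows, truncate, self the keepers.

    Public GS scenarios rank the nursery by GEBV and grow no phenotyped
    plots at this step; everything else phenotypes one off-season row per
    line.
    """
    cfg = state.config
    rng = state.rng
    _check_cohort(state, co, "nursery")
    n_fam = co.pop.n
    f2 = self_each(co.pop, np.arange(n_fam), cfg.progeny_per_self, rng,
                   cohort_tag="F2", birth_year=state.year,
                   id_start=state.take_ids(n_fam * cfg.progeny_per_self))
    f2.pool[:] = PRIVATE if co.pipeline == "private" else PUBLIC
    keep = cfg.nursery_keep(co.pipeline)
    use_gebv = (co.pipeline == "conv" and state.in_eval
                and state.effective_scenario in GS_SCENARIOS
                and state.model is not None)
    if use_gebv:
        scores = predict_gebv(state.model, f2)
    else:
        env = state.env.get(state.year, OFFSEASON)
        ph = phenotype(f2, state.trait, env, 1, rng)
        scores = ph["value"].to_numpy()
        state.log_phenotypes(co.uid, co.pipeline, "nursery", f2.n)
    rows = _top_rows(scores, f2.ids, keep)
    kept = f2.subset(rows)
    lines = self_each(kept, np.arange(keep), 1, rng, cohort_tag="F3",
                      birth_year=state.year, id_start=state.take_ids(keep))
    co.pop = lines
    co.scores = np.asarray(scores)[rows]


def _stage_testcross(state: ProgramState, co: Cohort, stage_idx: int):
    """TC1-TC3: hybrids against the tester set, entry-mean phenotypes in the
    target environment, GCA estimation, truncation to the next stage size."""
    cfg = state.config
    rng = state.rng
    stage = f"TC{stage_idx + 1}"
    _check_cohort(state, co, stage)
    n_testers = cfg.tc_testers[stage_idx]
    trials = cfg.tc_trials[stage_idx]
    testers = state.tester_set
    n_par = co.pop.n
    par_rows = np.repeat(np.arange(n_par), n_testers)
    tes_rows = np.tile(np.arange(n_testers), n_par)
    hybrids = cross_pairs(co.pop, par_rows, testers, tes_rows, rng,
                          cohort_tag="hybrid", birth_year=state.year,
                          id_start=state.take_ids(n_par * n_testers))
    env = state.env.get(state.year, TARGET)
    ph = phenotype(hybrids, state.trait, env, trials, rng)
    state.log_phenotypes(co.uid, co.pipeline, stage, hybrids.n)
    df = pd.DataFrame({
        "parent": co.pop.ids[par_rows],
        "tester": testers.ids[tes_rows],
        "value": ph["value"].to_numpy(),
    })
    gca = estimate_gca(df)["gca"].loc[co.pop.ids].to_numpy()

    if (state.in_eval and co.pipeline != "private"
            and state.effective_scenario in ("GSTC", "DHGS")):
        Z = co.pop.dosage(state.genome.snp_sites).astype(np.float64)
        state.training.add(Z, gca, co.pop.ids, state.year, tag=stage)

    if stage_idx == 0 and co.pipeline == "dh":
        state._tc1_snapshot = (co.pop, gca)
    if stage_idx == 1:
        state._tc2_snapshot = (co.pop, gca, co.pipeline)

    if stage_idx == 2:
        state._tc3_hybrid_mean = float(
            np.mean(genetic_value(hybrids, state.trait)))
        state._release_pool = (co.pop, gca)
        co.done = True
        return
    k_next = cfg.tc_parents(co.pipeline)[stage_idx + 1]
    rows = _top_rows(gca, co.pop.ids, k_next)
    surv = co.pop.subset(rows)
    surv_scores = gca[rows]
    if co.pipeline == "conv":
        surv = self_each(surv, np.arange(surv.n), 1, rng,
                         cohort_tag=f"F{4 + stage_idx}",
                         birth_year=state.year,
                         id_start=state.take_ids(surv.n))
    co.pop = surv
    co.scores = surv_scores


def _stage_private_trial(state: ProgramState, co: Cohort, stage_idx: int):
    """Private-program line trials: per-se entry-mean phenotypes in the
    target environment with the stage replicate counts, then truncation."""
    cfg = state.config
    rng = state.rng
    stage = f"PT{stage_idx + 1}"
    _check_cohort(state, co, stage)
    reps = cfg.tc_trials[stage_idx]
    env = state.env.get(state.year, TARGET)
    ph = phenotype(co.pop, state.trait, env, reps, rng)
    scores = ph["value"].to_numpy()
    state.log_phenotypes(co.uid, co.pipeline, stage, co.pop.n)
    if stage_idx == 1:
        pool = cfg.scaled(cfg.new_parent_pool_size) * cfg.private_scale
        rows = _top_rows(scores, co.pop.ids, min(pool, co.pop.n))
        state._private_candidates = (co.pop.subset(rows), scores[rows])
    if stage_idx == 2:
        rows = _top_rows(scores, co.pop.ids, cfg.private_releases)
        state._private_finished = co.pop.subset(rows)
        co.done = True
        return
    k_next = cfg.tc_parents("private")[stage_idx + 1]
    rows = _top_rows(scores, co.pop.ids, k_next)
    surv = self_each(co.pop.subset(rows), np.arange(k_next), 1, rng,
                     cohort_tag=f"F{4 + stage_idx}", birth_year=state.year,
                     id_start=state.take_ids(k_next))
    co.pop = surv
    co.scores = scores[rows]


# --------------------------------------------------------------------------
# yearly bookkeeping
# --------------------------------------------------------------------------

def _pair_block(n, rng, n_crosses=None):
    """Random crossing plan: each cross draws two distinct parents at
    random from the block. Contributions are unequal by design - the
    effective population size of a crossing block is below its census size,
    which is what makes full parental replacement erode diversity."""
    k = n if n_crosses is None else n_crosses
    mothers = rng.integers(0, n, size=k)
    fathers = rng.integers(0, n, size=k)
    clash = mothers == fathers
    while np.any(clash):
        fathers[clash] = rng.integers(0, n, size=int(clash.sum()))
        clash = mothers == fathers
    return mothers, fathers


def _gsf1_training(state: ProgramState):
    cfg = state.config
    rng = state.rng
    block = state.crossing_block
    k = cfg.scaled(cfg.f1_training_size)
    mothers = rng.integers(0, block.n, size=k)
    fathers = rng.integers(0, block.n, size=k)
    clash = mothers == fathers
    while np.any(clash):
        fathers[clash] = rng.integers(0, block.n, size=int(clash.sum()))
        clash = mothers == fathers
    f1 = cross_pairs(block, mothers, block, fathers, rng,
                     cohort_tag="F1train", birth_year=state.year,
                     id_start=state.take_ids(k))
    env = state.env.get(state.year, TARGET)
    ph = phenotype(f1, state.trait, env, 1, rng)
    state.log_phenotypes(-1, "conv", "F1train", f1.n)
    Z = f1.dosage(state.genome.snp_sites).astype(np.float64)
    state.training.add(Z, ph["value"].to_numpy(), f1.ids, state.year,
                       tag="F1")


def _public_candidates(state: ProgramState):
    """(pop, scores) of new-parent candidates under the scenario's rule."""
    scen = state.effective_scenario
    if scen == "DHGS":
        snap = state._tc1_snapshot
        if snap is None:
            return None
        pop, gca = snap
        if state.model is not None:
            return pop, predict_gebv(state.model, pop)
        return pop, gca
    snap = state._tc2_snapshot
    if snap is None:
        return None
    pop, gca, _pipeline = snap
    if scen in ("GSTC", "GSF1") and state.model is not None:
        return pop, predict_gebv(state.model, pop)
    return pop, gca


def _update_public_block(state: ProgramState):
    """Parental substitution, once per completed recurrent-selection cycle
    (every 5 years; 4 in the DH scenarios): the candidate pool is the top
    new lines of the cycle's final cohort, combined with parents of the
    immediately preceding cycle only."""
    cfg = state.config
    at_boundary = (state.eval_year % cfg.cycle_years == 0 if state.in_eval
                   else state.year % 5 == 0)
    if not at_boundary:
        return
    cand = _public_candidates(state)
    if cand is None:
        return
    pop, scores = cand
    pool = cfg.scaled(cfg.new_parent_pool_size)
    rows = _top_rows(scores, pop.ids, min(pool, pop.n))
    pool_pop = pop.subset(rows)
    pool_scores = np.asarray(scores)[rows]
    frac = cfg.old_fraction if state.in_eval else cfg.burnin_old_fraction
    state.crossing_block, state.block_scores = select_parents(
        state.crossing_block, state.block_scores, pool_pop, pool_scores,
        frac, cfg.n_crosses)


def _update_private_block(state: ProgramState):
    cfg = state.config
    if state.year % 5 != 0:  # the private program recycles per 5-year cycle
        return
    cand = state._private_candidates
    if cand is None:
        return
    pop, scores = cand
    # the private program's practice is fixed; only the public program's
    # substitution ratio is under study
    state.private_block, state.private_scores = select_parents(
        state.private_block, state.private_scores, pop, scores,
        cfg.burnin_old_fraction, cfg.private_scale * cfg.n_crosses)


def _new_public_cohort(state: ProgramState):
    cfg = state.config
    rng = state.rng
    block = state.crossing_block
    mothers, fathers = _pair_block(block.n, rng)
    f1 = cross_pairs(block, mothers, block, fathers, rng, cohort_tag="F1",
                     birth_year=state.year, id_start=state.take_ids(block.n))
    if state.effective_scenario in DH_SCENARIOS:
        per_family = max(cfg.scaled(cfg.dh_lines_total) // cfg.n_crosses, 1)
        dh = make_dh_each(f1, np.arange(f1.n), per_family, rng,
                          birth_year=state.year,
                          id_start=state.take_ids(f1.n * per_family))
        state.cohorts.append(Cohort(state.take_uid(), dh, "dh"))
    else:
        state.cohorts.append(Cohort(state.take_uid(), f1, "conv"))


def _new_private_cohort(state: ProgramState):
    cfg = state.config
    rng = state.rng
    block = state.private_block
    mothers, fathers = _pair_block(block.n, rng)
    f1 = cross_pairs(block, mothers, block, fathers, rng, cohort_tag="F1",
                     birth_year=state.year, id_start=state.take_ids(block.n))
    f1.pool[:] = PRIVATE
    state.cohorts.append(Cohort(state.take_uid(), f1, "private"))


def run_private_program(state: ProgramState):
    """Advance the private (tester-source) program by one year: trials on
    in-flight cohorts, block update, a new crossing, and tester turnover at
    cycle boundaries. Phenotypic truncation in every scenario."""
    cfg = state.config
    for co in sorted((c for c in state.cohorts
                      if c.pipeline == "private" and not c.done),
                     key=lambda c: (-c.age, c.uid)):
        if co.age == 1:
            _stage_nursery(state, co)
        elif 2 <= co.age <= 4:
            _stage_private_trial(state, co, co.age - 2)
    _update_private_block(state)
    _new_private_cohort(state)
    if state.year % 5 == 0 and state._private_finished is not None:
        state.tester_set = state._private_finished
    return state.tester_set


# --------------------------------------------------------------------------
# the yearly step
# --------------------------------------------------------------------------

def advance_year(state: ProgramState) -> ProgramState:
    """Execute one calendar year: all in-flight cohorts advance one stage."""
    cfg = state.config
    state.year += 1
    state.env.ensure_year(state.year)
    scen = state.effective_scenario

    for co in state.cohorts:
        co.age += 1
    state._tc1_snapshot = None
    state._tc2_snapshot = None
    state._tc3_hybrid_mean = math.nan
    state._release_pool = None
    state._private_candidates = None
    state._private_finished = None

    # 0. GSF1 training trial (target environment) before any selection
    if state.in_eval and scen == "GSF1":
        _gsf1_training(state)

    # 1. testcross stages on the public program, oldest cohorts first (a
    #    scenario's own pipeline overwrites transition-year snapshots)
    public = [c for c in state.cohorts if c.pipeline != "private"
              and not c.done]
    for co in sorted(public, key=lambda c: (-c.age, c.uid)):
        if co.pipeline == "conv" and 2 <= co.age <= 4:
            _stage_testcross(state, co, co.age - 2)
        elif co.pipeline == "dh" and 1 <= co.age <= 3:
            _stage_testcross(state, co, co.age - 1)

    # 2. refresh the marker model on the pruned window
    if state.in_eval and cfg.uses_gs:
        state.training.prune(state.year)
        if state.training.n_records >= 2:
            state.model = fit_rrblup(state.training)

    # 3. nursery steps (GEBV-ranked and unphenotyped in GS scenarios)
    for co in public:
        if co.pipeline == "conv" and co.age == 1:
            _stage_nursery(state, co)

    # 4. crossing-block update and the year's new crosses
    _update_public_block(state)
    _new_public_cohort(state)

    # 5. private program (trials, block, crossing, tester turnover)
    run_private_program(state)

    # 6. releases, booked once per completed cycle
    if (state.in_eval and state._release_pool is not None
            and state.eval_year % cfg.cycle_years == 0):
        pop, gca = state._release_pool
        rows = _top_rows(gca, pop.ids, cfg.releases_per_cycle)
        rel = pop.subset(rows)
        state.released.append(dict(
            year=state.year, eval_year=state.eval_year,
            ids=rel.ids.tolist(),
            genetic_values=genetic_value(rel, state.trait).tolist()))
        state.n_released_eval += cfg.releases_per_cycle

    state.cohorts = [c for c in state.cohorts if not c.done]

    if state.in_eval:
        state.metrics.append(_metric_row(state))
    return state


def _metric_row(state: ProgramState) -> dict:
    cfg = state.config
    gv = genetic_value(state.crossing_block, state.trait)
    try:
        annual = economics.annual_cost(cfg.scenario, cfg.n_crosses)
    except KeyError:
        annual = math.nan
    return dict(
        year=state.eval_year,
        parental_genetic_mean=float(gv.mean()),
        parental_genetic_variance=float(gv.var(ddof=1)),
        hybrid_genetic_mean=state._tc3_hybrid_mean,
        cumulative_cost=state.eval_year * annual,
        n_released=state.n_released_eval,
    )


# --------------------------------------------------------------------------
# entry points
# --------------------------------------------------------------------------

def _derive_streams(seed):
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence(int(seed))
    founder_ss, burn_ss, eval_ss, env_ss = ss.spawn(4)
    return (np.random.default_rng(founder_ss), np.random.default_rng(burn_ss),
            np.random.default_rng(eval_ss), np.random.default_rng(env_ss))


def run_burnin(config: ScenarioConfig, seed) -> ProgramState:
    """Found the program and run the 15-year conventional burn-in.

    The result depends only on the shared (scenario-independent) part of the
    configuration, so two scenarios with the same seed return bit-identical
    states.
    """
    rng_f, rng_burn, rng_eval, rng_env = _derive_streams(seed)
    spec = GenomeSpec.create(rng_f, **config.genome_spec_kwargs())
    founders = simulate_founders(spec, config.n_founders,
                                 config.split_generations, rng_f,
                                 method=config.founder_method)
    trait = build_trait(founders, ge_var_multiplier=config.ge_multiplier,
                        residual_var=config.residual_var, rng=rng_f)
    env = EnvironmentTable(rng_env)
    state = ProgramState(config, founders.genome, trait, founders,
                         rng_burn, rng_eval, env)
    state._seed_repr = seed
    for _ in range(config.burn_in_years):
        advance_year(state)
    # burn-in baseline row (evaluation year 0)
    gv = genetic_value(state.crossing_block, state.trait)
    state.metrics.append(dict(
        year=0, parental_genetic_mean=float(gv.mean()),
        parental_genetic_variance=float(gv.var(ddof=1)),
        hybrid_genetic_mean=state._tc3_hybrid_mean,
        cumulative_cost=0.0, n_released=0))
    return state


def evaluate(state: ProgramState) -> RunResult:
    """Run the evaluation phase on a (possibly copied) post-burn-in state."""
    state.rng = state._rng_eval
    for _ in range(state.config.eval_years):
        advance_year(state)
    metrics = pd.DataFrame(state.metrics).sort_values("year")
    metrics = metrics.reset_index(drop=True)
    seed = getattr(state, "_seed_repr", None)
    if isinstance(seed, np.random.SeedSequence):
        seed = seed.entropy if isinstance(seed.entropy, int) else -1
    return RunResult(scenario=state.config.scenario, seed=seed,
                     metrics=metrics, released=state.released,
                     config=state.config)


def run_scenario(config: ScenarioConfig, seed) -> RunResult:
    """Burn-in plus 20 evaluation years; deterministic for a fixed seed."""
    return evaluate(run_burnin(config, seed))


def run_scenarios_shared(configs: dict, seed) -> dict:
    """Run several scenario variants from one shared burn-in state.

    ``configs`` maps labels to ScenarioConfigs agreeing on all shared
    (burn-in-relevant) fields. Returns {label: RunResult}.
    """
    configs = dict(configs)
    labels = list(configs)
    base = configs[labels[0]]
    for cfg in configs.values():
        if cfg.shared_key() != base.shared_key():
            raise ValueError("configs do not share burn-in-relevant fields")
    state0 = run_burnin(base, seed)
    out = {}
    for label in labels:
        st = state0.copy()
        st.config = configs[label]
        out[label] = evaluate(st)
    return out
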