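"""Replicated runs, aggregation, presets and file I/O.

Replicate r of a batch uses the numpy seed sequence (base_seed, r), so a
batch is a pure function of (config, base_seed) regardless of execution
order. Aggregates report per-(scenario, year) means and sample standard
deviations over replicates; the human-readable report uses the
"mean (sd)" cell convention, CSV outputs never do.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .pipeline import (RunResult, ScenarioConfig, evaluate, run_burnin,
                       run_scenario)

__all__ = [
    "desk_preset",
    "make_config",
    "load_config",
    "replicate_seed",
    "run_replicates",
    "run_paired_replicates",
    "aggregate",
    "format_mean_sd",
    "write_run_csv",
    "read_run_csv",
]

METRIC_COLUMNS = ("parental_genetic_mean", "parental_genetic_variance",
                  "hybrid_genetic_mean", "cumulative_cost", "n_released")

#: reduced problem size for desk-scale experiments: 3 chromosome pairs with
#: 50 QTN and 500 SNPs each (stage sizes and calendars unchanged)
DESK_GENOME = dict(n_chromosomes=3, qtn_per_chr=50, snp_per_chr=500)


def desk_preset(**overrides) -> ScenarioConfig:
    kw = dict(DESK_GENOME)
    kw.update(overrides)
    return ScenarioConfig(**kw)


def make_config(preset: str = "full", **overrides) -> ScenarioConfig:
    if preset == "desk":
        return desk_preset(**overrides)
    if preset == "full":
        return ScenarioConfig(**overrides)
    raise ValueError(f"unknown preset {preset!r}")


def load_config(path, **overrides) -> ScenarioConfig:
    """Build a ScenarioConfig from a YAML mapping of field names (an
    optional ``preset`` key selects desk/full defaults first)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    preset = data.pop("preset", "full")
    for key in ("tc_testers", "tc_trials", "conv_tc_parents",
                "dh_tc_parents"):
        if key in data:
            data[key] = tuple(data[key])
    data.update(overrides)
    return make_config(preset, **data)


def replicate_seed(base_seed: int, r: int) -> np.random.SeedSequence:
    """Stable derivation of replicate r's seed from the batch seed."""
    return np.random.SeedSequence([int(base_seed), int(r)])


def run_replicates(config: ScenarioConfig, n_reps: int = 50,
                   base_seed: int = 0) -> list:
    """Independent replicates; failures are recorded (with their seed) and
    do not abort the remaining replicates."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    out = []
    for r in range(n_reps):
        ss = replicate_seed(base_seed, r)
        try:
            res = run_scenario(config, ss)
            res.seed = r
            out.append(res)
        except Exception as exc:  # noqa: BLE001 - replicate isolation
            out.append(dict(replicate=r, base_seed=base_seed, error=str(exc)))
    return out


def run_paired_replicates(configs: dict, n_reps: int, base_seed: int = 0
                          ) -> dict:
    """Paired scenario comparison: replicate r shares founders, trait,
    burn-in and environment draws across all configs (which must agree on
    the burn-in-relevant fields). Returns {label: [RunResult, ...]}."""
    labels = list(configs)
    out = {lab: [] for lab in labels}
    base = configs[labels[0]]
    for cfg in configs.values():
        if cfg.shared_key() != base.shared_key():
            raise ValueError("paired configs must share burn-in fields")
    for r in range(n_reps):
        ss = replicate_seed(base_seed, r)
        state0 = run_burnin(base, ss)
        for lab in labels:
            st = state0.copy()
            st.config = configs[lab]
            res = evaluate(st)
            res.seed = r
            out[lab].append(res)
    return out


# --------------------------------------------------------------------------
# aggregation
# --------------------------------------------------------------------------

def aggregate(results) -> pd.DataFrame:
    """Per-(scenario, year) mean and sample sd of each metric."""
    results = [r for r in results if isinstance(r, RunResult)]
    if not results:
        raise ValueError("no successful results to aggregate")
    frames = []
    for res in results:
        df = res.metrics.copy()
        df["scenario"] = res.scenario
        df["replicate"] = res.seed
        frames.append(df)
    allm = pd.concat(frames, ignore_index=True)
    grouped = allm.groupby(["scenario", "year"])
    agg = grouped[list(METRIC_COLUMNS)].agg(["mean", "std"])
    agg.columns = [f"{m}_{s}" for m, s in agg.columns]
    agg["n_replicates"] = grouped.size()
    agg = agg.fillna({c: 0.0 for c in agg.columns if c.endswith("_std")})
    return agg.reset_index()


def format_mean_sd(agg: pd.DataFrame, metric: str, digits: int = 1
                   ) -> pd.DataFrame:
    """Human-readable "mean (sd)" table, scenarios x years."""
    cells = agg.apply(
        lambda r: f"{r[f'{metric}_mean']:.{digits}f} "
                  f"({r[f'{metric}_std']:.{digits}f})", axis=1)
    out = agg[["scenario", "year"]].copy()
    out["cell"] = cells
    return out.pivot(index="scenario", columns="year", values="cell")


# --------------------------------------------------------------------------
# CSV round trip
# --------------------------------------------------------------------------

_CSV_META = ("scenario", "replicate")


def write_run_csv(res: RunResult, path) -> None:
    df = res.metrics.copy()
    df.insert(0, "scenario", res.scenario)
    df.insert(1, "replicate", res.seed)
    df.to_csv(path, index=False)


def read_run_csv(path) -> RunResult:
    df = pd.read_csv(path)
    missing = set(_CSV_META + ("year",) + METRIC_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"run CSV missing columns: {sorted(missing)}")
    scenario = df["scenario"].iloc[0]
    replicate = int(df["replicate"].iloc[0])
    metrics = df.drop(columns=list(_CSV_META)).reset_index(drop=True)
    return RunResult(scenario=scenario, seed=replicate, metrics=metrics,
                     released=[], config=None)
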