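"""Quantitative trait: additive + dominance + genotype-by-environment.

The trait is anchored to the founder population: after scaling, the founder
additive values have mean 150 and variance 30 exactly (population variance on
the founder set used for scaling). Dominance effects follow the
degree-of-dominance convention d_i = delta_i * |a_i| with
delta_i ~ Normal(0.93, 0.3) (variance 0.3). GE interaction is a linear
reaction norm: a per-individual sensitivity score (QTN-based slope effects)
multiplied by a yearly environmental covariate, with the founder slope-score
variance scaled to ``ge_var_multiplier`` x 30 at a unit-variance covariate.

Environmental covariates are drawn per (year, season) as quantiles and mapped
through the standard-normal inverse CDF: the target season uses quantile
draws ~ Normal(0.5, 0.03) (EC near 0) and the off-season uses
Normal(0.1 or 0.9 by a fair coin per year, 0.03) (EC near -1.28 or +1.28),
so the base covariate has mean 0 and variance 1 across typical years.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .genome import Population

__all__ = [
    "TraitArchitecture",
    "EnvironmentContext",
    "EnvironmentTable",
    "build_trait",
    "rescale_trait",
    "additive_value",
    "genetic_value",
    "ge_deviation",
    "phenotype",
]

TARGET = "target"
OFFSEASON = "offseason"


@dataclasses.dataclass
class TraitArchitecture:
    """QTN effect sets plus the scaling constants that anchor them."""

    qtn_add: np.ndarray          # additive effects a_i (scaled)
    dom_degree: np.ndarray       # delta_i; dominance effect is delta_i*|a_i|
    ge_slope: np.ndarray         # reaction-norm slope effects s_i (scaled)
    intercept: float
    ge_var_multiplier: float = 0.0
    residual_var: float = 240.0  # 60 = high heritability, 240 = low
    target_mean: float = 150.0
    target_additive_var: float = 30.0
    dom_degree_mean: float = 0.93
    dom_degree_var: float = 0.3

    @property
    def dom_effects(self) -> np.ndarray:
        return self.dom_degree * np.abs(self.qtn_add)

    @property
    def n_qtn(self) -> int:
        return self.qtn_add.size


def _qtn_coding(pop: Population):
    """(-1, 0, 1) genotype coding and heterozygote indicator at QTN."""
    x = pop.dosage(pop.genome.qtn_sites).astype(np.float64) - 1.0
    h = pop.heterozygous(pop.genome.qtn_sites).astype(np.float64)
    return x, h


def build_trait(founders: Population, *, ge_var_multiplier: float = 0.0,
                residual_var: float = 240.0, target_mean: float = 150.0,
                target_additive_var: float = 30.0, dom_degree_mean: float = 0.93,
                dom_degree_var: float = 0.3, rng=None) -> TraitArchitecture:
    """Draw raw effects and scale them on the founder set.

    Raw additive effects and GE slopes are independent standard normals per
    QTN; dominance degrees ~ Normal(dom_degree_mean, dom_degree_var).
    """
    rng = np.random.default_rng(rng)
    n_qtn = founders.genome.qtn_sites.size
    trait = TraitArchitecture(
        qtn_add=rng.standard_normal(n_qtn),
        dom_degree=rng.normal(dom_degree_mean, np.sqrt(dom_degree_var), n_qtn),
        ge_slope=rng.standard_normal(n_qtn),
        intercept=0.0,
        ge_var_multiplier=ge_var_multiplier,
        residual_var=residual_var,
        target_mean=target_mean,
        target_additive_var=target_additive_var,
        dom_degree_mean=dom_degree_mean,
        dom_degree_var=dom_degree_var)
    return rescale_trait(trait, founders)


def rescale_trait(trait: TraitArchitecture, founders: Population
                  ) -> TraitArchitecture:
    """Scale effects so the founder additive mean/variance hit their targets
    exactly and the founder slope score has variance multiplier x target
    additive variance. Idempotent: re-applying to a scaled trait is a no-op
    (up to floating point)."""
    x, _ = _qtn_coding(founders)
    score = x @ trait.qtn_add
    var = score.var()
    if var <= 1e-10 * (1.0 + float(np.mean(score)) ** 2):
        raise ValueError("founder additive variance is zero before scaling; "
                         "founders must segregate at the QTN")
    c = np.sqrt(trait.target_additive_var / var)
    a = trait.qtn_add * c
    intercept = trait.target_mean - float(np.mean(x @ a))
    if trait.ge_var_multiplier > 0:
        gescore = x @ trait.ge_slope
        gvar = gescore.var()
        if gvar <= 0:
            raise ValueError("founder GE slope variance is zero before scaling")
        target = trait.ge_var_multiplier * trait.target_additive_var
        s = trait.ge_slope * np.sqrt(target / gvar)
    else:
        s = np.zeros_like(trait.ge_slope)
    return dataclasses.replace(trait, qtn_add=a, ge_slope=s,
                               intercept=intercept)


def additive_value(pop: Population, trait: TraitArchitecture) -> np.ndarray:
    x, _ = _qtn_coding(pop)
    return trait.intercept + x @ trait.qtn_add


def genetic_value(pop: Population, trait: TraitArchitecture) -> np.ndarray:
    """Additive + dominance genetic value (no environment, no error)."""
    x, h = _qtn_coding(pop)
    return trait.intercept + x @ trait.qtn_add + h @ trait.dom_effects


def ge_deviation(pop: Population, trait: TraitArchitecture,
                 env: "EnvironmentContext") -> np.ndarray:
    """Reaction-norm deviation: slope score x environmental covariate."""
    x, _ = _qtn_coding(pop)
    return (x @ trait.ge_slope) * env.ec_value


# --------------------------------------------------------------------------
# environments
# --------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class EnvironmentContext:
    year: int
    env_class: str  # "target" | "offseason"
    ec_value: float


class EnvironmentTable:
    """One covariate draw per (year, season), cached so every phenotype in
    the same year/season shares it."""

    def __init__(self, rng=None):
        self._rng = np.random.default_rng(rng)
        self._cache: dict[tuple[int, str], EnvironmentContext] = {}

    def ensure_year(self, year: int) -> None:
        """Draw both seasons for ``year`` in a fixed order (keeps covariate
        sequences identical across scenario variants sharing an RNG seed)."""
        self.get(year, TARGET)
        self.get(year, OFFSEASON)

    def get(self, year: int, env_class: str) -> EnvironmentContext:
        key = (year, env_class)
        if key not in self._cache:
            if env_class == TARGET:
                q = self._rng.normal(0.5, 0.03)
            elif env_class == OFFSEASON:
                center = 0.1 if self._rng.random() < 0.5 else 0.9
                q = self._rng.normal(center, 0.03)
            else:
                raise ValueError(f"unknown env_class: {env_class!r}")
            ec = float(ndtri(np.clip(q, 1e-9, 1 - 1e-9)))
            self._cache[key] = EnvironmentContext(year, env_class, ec)
        return self._cache[key]


# --------------------------------------------------------------------------
# phenotypes
# --------------------------------------------------------------------------

def phenotype(pop: Population, trait: TraitArchitecture,
              env: EnvironmentContext, n_reps: int, rng) -> pd.DataFrame:
    """Entry-mean phenotypes: genetic value + GE deviation + error with
    variance residual_var / n_reps (error shrinks with replicate count)."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    g = genetic_value(pop, trait)
    if trait.ge_var_multiplier > 0:
        g = g + ge_deviation(pop, trait, env)
    err_sd = np.sqrt(trait.residual_var / n_reps)
    value = g + rng.normal(0.0, err_sd, size=pop.n) if err_sd > 0 else g
    return pd.DataFrame({
        "id": pop.ids,
        "year": env.year,
        "env_class": env.env_class,
        "n_reps": n_reps,
        "value": value,
    })
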