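"""Seeded generators for synthetic study databases and elicitation grids.

The generators emulate the statistical structure of large meta-analytic
collections of psychology hypothesis tests: a correlation database (855
records, sample sizes 10-500) and a t-test database (855 records in a
85/604/166 one-sample/paired/independent mix, per-group sample sizes 2-212
with median 24). Effects come from a configurable mixture of a point null and
a prior over the effect size; sample correlations are produced by simulating
raw bivariate-normal data (keeping the generator independent of the analytic
likelihood used by the Bayes-factor engine), t statistics by exact
noncentral-t construction from normal and chi-square draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .priors import ElicitationGrid, PriorSpec, _grid_bin_probs, sample_prior

__all__ = [
    "GeneratorConfig",
    "default_correlation_config",
    "default_ttest_config",
    "gen_correlation_db",
    "gen_ttest_db",
    "gen_elicitation_grid",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of a synthetic study database.

    Effects follow one of three models: ``fixed`` (all studies share
    ``effect_value``), ``from_prior`` (drawn from ``effect_prior``), or
    ``two_component`` (a ``null_prop`` fraction of studies are exact nulls,
    the rest draw from ``effect_prior``). Sample sizes are log-uniform
    integers on [n_min, n_max]; when ``n_median_target`` is set, half the
    mass is placed log-uniformly on each side of the target so the population
    median equals it. The t-test ``design_mix`` gives the proportions of
    one-sample, paired and independent designs.
    """

    seed: int
    n_studies: int = 855
    effect_model: str = "two_component"  # fixed | from_prior | two_component
    effect_value: float = 0.0
    effect_prior: PriorSpec | None = None
    null_prop: float = 0.5
    n_min: int = 10
    n_max: int = 500
    n_median_target: int | None = None
    design_mix: tuple[float, float, float] = (85 / 855, 604 / 855, 166 / 855)

    def __post_init__(self) -> None:
        if self.n_studies < 1:
            raise ValueError("n_studies must be positive")
        if self.effect_model not in ("fixed", "from_prior", "two_component"):
            raise ValueError(f"unknown effect model {self.effect_model!r}")
        if self.effect_model != "fixed" and self.effect_prior is None:
            raise ValueError("effect model needs an effect_prior")
        if not 0 <= self.null_prop <= 1:
            raise ValueError("null_prop must be in [0, 1]")
        if self.n_min < 2 or self.n_max < self.n_min:
            raise ValueError("need 2 <= n_min <= n_max")
        if abs(sum(self.design_mix) - 1) > 1e-9:
            raise ValueError("design_mix must sum to 1")


def default_correlation_config(seed: int) -> GeneratorConfig:
    """Default correlation database: 855 studies, n in [10, 500], 50% nulls,
    effects from a Beta(2, 5) population of correlations (median r near 0.15)."""
    return GeneratorConfig(
        seed=seed,
        n_studies=855,
        effect_model="two_component",
        null_prop=0.5,
        effect_prior=PriorSpec("beta", {"alpha": 2.0, "beta": 5.0}, "population (rho)"),
        n_min=10,
        n_max=500,
    )


def default_ttest_config(seed: int) -> GeneratorConfig:
    """Default t-test database: 855 studies in the 85/604/166 design mix,
    per-group n in [2, 212] with median 24, 50% nulls, effects from a broad
    truncated-t population on delta."""
    return GeneratorConfig(
        seed=seed,
        n_studies=855,
        effect_model="two_component",
        null_prop=0.5,
        effect_prior=PriorSpec(
            "t_truncated", {"mu": 0.5, "sigma": 0.25, "nu": 5.0}, "population (delta)"
        ),
        n_min=2,
        n_max=212,
        n_median_target=24,
    )


def _draw_effects(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    k = config.n_studies
    if config.effect_model == "fixed":
        return np.full(k, config.effect_value)
    effects = sample_prior(config.effect_prior, k, rng)
    if config.effect_model == "two_component":
        nulls = rng.uniform(size=k) < config.null_prop
        effects = np.where(nulls, 0.0, effects)
    return effects


def _draw_sizes(config: GeneratorConfig, rng: np.random.Generator, k: int) -> np.ndarray:
    lo, hi = math.log(config.n_min), math.log(config.n_max)
    if config.n_median_target is None:
        logs = rng.uniform(lo, hi, size=k)
    else:
        mid = math.log(config.n_median_target)
        side = rng.uniform(size=k) < 0.5
        logs = np.where(
            side, rng.uniform(lo, mid, size=k), rng.uniform(mid, hi, size=k)
        )
    return np.clip(np.rint(np.exp(logs)).astype(int), config.n_min, config.n_max)


def gen_correlation_db(config: GeneratorConfig) -> pd.DataFrame:
    """Synthetic correlation database in the study_db schema (n1 = n2 = n).

    For each study a population correlation rho is drawn from the effect
    model, a sample size n from the size model, and the sample correlation r
    is computed from n simulated bivariate-normal pairs.
    """
    rng = np.random.default_rng(config.seed)
    rhos = _draw_effects(config, rng)
    if np.any((rhos < -1) | (rhos > 1)):
        raise ValueError("correlation effects must lie in [-1, 1]")
    sizes = _draw_sizes(config, rng, config.n_studies)
    rs = np.empty(config.n_studies)
    for i, (rho, n) in enumerate(zip(rhos, sizes)):
        x = rng.standard_normal(n)
        y = rho * x + math.sqrt(1 - rho * rho) * rng.standard_normal(n)
        rs[i] = np.corrcoef(x, y)[0, 1]
    width = len(str(config.n_studies))
    return pd.DataFrame(
        {
            "study_id": [f"S{i + 1:0{width}d}" for i in range(config.n_studies)],
            "r": rs,
            "n1": sizes,
            "n2": sizes,
        }
    )


_DESIGNS = ("one_sample", "paired", "independent")


def _design_counts(mix: tuple[float, float, float], k: int) -> np.ndarray:
    """Largest-remainder apportionment of k studies to the three designs."""
    raw = np.asarray(mix) * k
    counts = np.floor(raw).astype(int)
    rem = k - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:rem]] += 1
    return counts


def gen_ttest_db(config: GeneratorConfig) -> pd.DataFrame:
    """Synthetic t-test database in the study_db schema.

    Deltas come from the effect model; the t statistic is built exactly as
    (Z + delta * sqrt(n_eff)) / sqrt(chi2_df / df) with the engine's design
    conventions (one-sample/paired: df = n1 - 1, n_eff = n1; independent:
    df = n1 + n2 - 2, n_eff = n1 n2 / (n1 + n2)).
    """
    rng = np.random.default_rng(config.seed)
    deltas = _draw_effects(config, rng)
    counts = _design_counts(config.design_mix, config.n_studies)
    designs = np.repeat(np.array(_DESIGNS, dtype=object), counts)
    rng.shuffle(designs)
    n1 = _draw_sizes(config, rng, config.n_studies)
    n2 = _draw_sizes(config, rng, config.n_studies)
    rows = []
    width = len(str(config.n_studies))
    for i in range(config.n_studies):
        design = designs[i]
        if design == "independent":
            df = n1[i] + n2[i] - 2
            n_eff = n1[i] * n2[i] / (n1[i] + n2[i])
            m2 = int(n2[i])
        else:
            df = n1[i] - 1
            if df < 1:  # one-sample/paired need n >= 2 -> guaranteed by n_min >= 2
                df = 1
            n_eff = float(n1[i])
            m2 = np.nan
        nc = deltas[i] * math.sqrt(n_eff)
        t = (rng.standard_normal() + nc) / math.sqrt(rng.chisquare(df) / df)
        rows.append(
            {
                "study_id": f"T{i + 1:0{width}d}",
                "design": design,
                "t": t,
                "n1": int(n1[i]),
                "n2": m2,
            }
        )
    return pd.DataFrame(rows, columns=["study_id", "design", "t", "n1", "n2"])


def gen_elicitation_grid(
    prior: PriorSpec,
    total_chips: int = 20,
    seed: int | None = None,
    mode: str = "deterministic",
) -> ElicitationGrid:
    """An elicitation grid a perfectly calibrated expert would produce.

    ``deterministic`` mode places expected (fractional) chip counts
    proportional to the prior's bin probabilities; ``stochastic`` mode draws
    integer chips from the corresponding multinomial (seeded).
    """
    if total_chips < 1:
        raise ValueError("total_chips must be >= 1")
    if prior.is_point:
        raise ValueError("point priors have no histogram representation")
    edges = np.linspace(0.0, 1.0, 11)
    probs = _grid_bin_probs(prior, edges)
    if not np.all(np.isfinite(probs)):
        raise ValueError("prior places no mass on the elicitation range")
    if mode == "deterministic":
        chips = probs * total_chips
    elif mode == "stochastic":
        rng = np.random.default_rng(seed)
        chips = rng.multinomial(total_chips, probs / probs.sum()).astype(float)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return ElicitationGrid(bin_edges=tuple(edges), chips=tuple(chips))
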