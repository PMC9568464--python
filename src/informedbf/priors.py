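"""Effect-size priors: parametric specifications, evaluation, and elicitation fits.

Two families of analyses are supported by the registry: priors on the Pearson
correlation ``rho`` (beta distributions on [0, 1], a uniform default, a point
null) and priors on Cohen's ``delta`` (shifted-scaled t distributions truncated
to ``delta > 0``, a positive-only Cauchy default, a point null). All truncated
families are renormalized by the untruncated mass on the support.

The elicitation side implements the histogram ("roulette") method: an expert
distributes chips over ten equal-width bins spanning the plausible effect-size
range, and a parametric distribution is fitted to the chip proportions by least
squares on bin probabilities.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy import integrate, optimize, stats

__all__ = [
    "PriorSpec",
    "ElicitationGrid",
    "UnderDeterminedFitWarning",
    "expert_registry",
    "prior_pdf",
    "prior_logpdf",
    "make_logpdf",
    "prior_cdf",
    "prior_mass_above",
    "prior_quantile",
    "sample_prior",
    "normalization_integral",
    "rho_priors",
    "delta_priors",
    "fit_prior_to_grid",
    "registry_to_json",
    "registry_from_json",
]

_FAMILIES = (
    "beta",
    "t_truncated",
    "normal_truncated",
    "cauchy_truncated",
    "uniform",
    "point",
)


class UnderDeterminedFitWarning(UserWarning):
    """Raised when an elicitation grid carries too little information for the family."""


@dataclass(frozen=True)
class PriorSpec:
    """A parametric prior on an effect-size parameter.

    Parameters
    ----------
    family
        One of ``beta`` (on rho in [0, 1]), ``t_truncated`` (shifted-scaled t on
        delta, truncated to delta > 0), ``normal_truncated``, ``cauchy_truncated``
        (location 0, truncated to delta > 0), ``uniform``, ``point``.
    params
        Family-specific parameters, e.g. ``{"alpha": 5.32, "beta": 18.58}``.
    label
        Free-text identifier, e.g. ``"Expert 2 (beta)"``.
    """

    family: str
    params: Mapping[str, float]
    label: str = ""

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown prior family {self.family!r}")
        object.__setattr__(self, "params", dict(self.params))
        p = self.params
        if self.family == "beta":
            if p["alpha"] <= 0 or p["beta"] <= 0:
                raise ValueError("beta prior requires alpha > 0 and beta > 0")
        elif self.family == "t_truncated":
            if p["sigma"] <= 0 or p["nu"] <= 0:
                raise ValueError("t prior requires sigma > 0 and nu > 0")
        elif self.family == "normal_truncated":
            if p["sigma"] <= 0:
                raise ValueError("normal prior requires sigma > 0")
        elif self.family == "cauchy_truncated":
            if p["scale"] <= 0:
                raise ValueError("Cauchy prior requires scale > 0")
        elif self.family == "uniform":
            if not p["lower"] < p["upper"]:
                raise ValueError("uniform prior requires lower < upper")

    @property
    def support(self) -> tuple[float, float]:
        if self.family == "beta":
            return (0.0, 1.0)
        if self.family in ("t_truncated", "normal_truncated", "cauchy_truncated"):
            return (0.0, math.inf)
        if self.family == "uniform":
            return (self.params["lower"], self.params["upper"])
        return (self.params["value"], self.params["value"])

    @property
    def is_point(self) -> bool:
        return self.family == "point"

    def _frozen(self):
        """The untruncated scipy distribution backing this prior (None for point)."""
        p = self.params
        if self.family == "beta":
            return stats.beta(p["alpha"], p["beta"])
        if self.family == "t_truncated":
            return stats.t(df=p["nu"], loc=p["mu"], scale=p["sigma"])
        if self.family == "normal_truncated":
            return stats.norm(loc=p["mu"], scale=p["sigma"])
        if self.family == "cauchy_truncated":
            return stats.cauchy(loc=0.0, scale=p["scale"])
        if self.family == "uniform":
            return stats.uniform(loc=p["lower"], scale=p["upper"] - p["lower"])
        return None

    @property
    def truncation_mass(self) -> float:
        """Mass the untruncated density places on the support (1 if not truncated)."""
        if self.family in ("t_truncated", "normal_truncated", "cauchy_truncated"):
            return float(self._frozen().sf(0.0))
        return 1.0

    def mode(self) -> float:
        """Location of the density maximum on the support."""
        p = self.params
        if self.family == "point":
            return p["value"]
        if self.family == "beta":
            a, b = p["alpha"], p["beta"]
            if a > 1 and b > 1:
                return (a - 1) / (a + b - 2)
            if a <= 1 and b > 1:
                return 0.0
            if a > 1 and b <= 1:
                return 1.0
            return 0.0 if a < b else 1.0
        if self.family in ("t_truncated", "normal_truncated"):
            return max(p["mu"], 0.0)
        if self.family == "cauchy_truncated":
            return 0.0
        return 0.5 * (p["lower"] + p["upper"])

    def to_dict(self) -> dict:
        lo, hi = self.support
        return {
            "label": self.label,
            "family": self.family,
            "params": dict(self.params),
            "support": [lo, None if math.isinf(hi) else hi],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PriorSpec":
        return cls(family=d["family"], params=d["params"], label=d.get("label", ""))


def prior_logpdf(spec: PriorSpec, x) -> np.ndarray | float:
    """Log density of ``spec`` at ``x``; ``-inf`` outside the support."""
    if spec.is_point:
        raise ValueError("point priors have no density; handle analytically")
    x = np.asarray(x, dtype=float)
    lo, hi = spec.support
    inside = (x >= lo) & (x <= hi)
    out = np.full(x.shape, -np.inf)
    frozen = spec._frozen()
    with np.errstate(divide="ignore"):
        out[inside] = frozen.logpdf(x[inside]) - math.log(spec.truncation_mass)
    return out if out.ndim else float(out)


def make_logpdf(spec: PriorSpec) -> Callable:
    """Closure evaluating the prior log density with precomputed constants.

    Equivalent to :func:`prior_logpdf` but avoids per-call scipy dispatch,
    which matters inside adaptive quadrature. Accepts scalars or arrays
    strictly inside the support (endpoints map to ``-inf``).
    """
    if spec.is_point:
        raise ValueError("point priors have no density; handle analytically")
    p = spec.params
    from scipy.special import betaln, gammaln

    if spec.family == "beta":
        a, b = p["alpha"], p["beta"]
        const = -betaln(a, b)

        def logpdf(x):
            with np.errstate(divide="ignore", invalid="ignore"):
                out = (a - 1) * np.log(x) + (b - 1) * np.log1p(-x) + const
            return np.where((x < 0) | (x > 1), -np.inf, out)

    elif spec.family == "t_truncated":
        mu, sigma, nu = p["mu"], p["sigma"], p["nu"]
        const = (
            gammaln((nu + 1) / 2)
            - gammaln(nu / 2)
            - 0.5 * math.log(nu * math.pi)
            - math.log(sigma)
            - math.log(spec.truncation_mass)
        )

        def logpdf(x):
            z = (np.asarray(x, dtype=float) - mu) / sigma
            out = const - (nu + 1) / 2 * np.log1p(z * z / nu)
            return np.where(np.asarray(x) < 0, -np.inf, out)

    elif spec.family == "normal_truncated":
        mu, sigma = p["mu"], p["sigma"]
        const = -math.log(sigma) - 0.5 * math.log(2 * math.pi) - math.log(
            spec.truncation_mass
        )

        def logpdf(x):
            z = (np.asarray(x, dtype=float) - mu) / sigma
            out = const - 0.5 * z * z
            return np.where(np.asarray(x) < 0, -np.inf, out)

    elif spec.family == "cauchy_truncated":
        gamma = p["scale"]
        const = -math.log(math.pi * gamma) - math.log(spec.truncation_mass)

        def logpdf(x):
            z = np.asarray(x, dtype=float) / gamma
            out = const - np.log1p(z * z)
            return np.where(np.asarray(x) < 0, -np.inf, out)

    else:  # uniform
        lo, hi = p["lower"], p["upper"]
        const = -math.log(hi - lo)

        def logpdf(x):
            x = np.asarray(x, dtype=float)
            return np.where((x < lo) | (x > hi), -np.inf, const)

    return logpdf


def prior_pdf(spec: PriorSpec, x) -> np.ndarray | float:
    """Density of ``spec`` at ``x``; 0 outside the support; truncated families renormalized."""
    out = np.exp(prior_logpdf(spec, x))
    return out if isinstance(out, np.ndarray) and out.ndim else float(out)


def prior_cdf(spec: PriorSpec, x) -> float:
    """P(theta <= x) under ``spec`` (point priors included)."""
    x = float(x)
    if spec.is_point:
        return 1.0 if x >= spec.params["value"] else 0.0
    lo, _ = spec.support
    frozen = spec._frozen()
    if x <= lo:
        return 0.0
    return float(min((frozen.cdf(x) - frozen.cdf(lo)) / spec.truncation_mass, 1.0))


def prior_mass_above(spec: PriorSpec, cutoff: float) -> float:
    """P(theta > cutoff) under ``spec``, in [0, 1]."""
    if spec.is_point:
        return 1.0 if spec.params["value"] > cutoff else 0.0
    return 1.0 - prior_cdf(spec, cutoff)


def prior_quantile(spec: PriorSpec, q: float) -> float:
    """Quantile function of the (truncated) prior."""
    if spec.is_point:
        return spec.params["value"]
    frozen = spec._frozen()
    lo, _ = spec.support
    base = frozen.cdf(lo)
    return float(frozen.ppf(base + q * spec.truncation_mass))


def sample_prior(spec: PriorSpec, size: int, rng: np.random.Generator) -> np.ndarray:
    """Seeded draws from the prior (inverse-CDF for truncated families)."""
    if spec.is_point:
        return np.full(size, spec.params["value"])
    u = rng.uniform(size=size)
    frozen = spec._frozen()
    lo, _ = spec.support
    base = frozen.cdf(lo)
    return np.asarray(frozen.ppf(base + u * spec.truncation_mass), dtype=float)


def normalization_integral(spec: PriorSpec) -> float:
    """Numeric integral of the density over the support (should be 1)."""
    lo, hi = spec.support
    if spec.is_point:
        return 1.0
    f = lambda x: prior_pdf(spec, x)
    val, _ = integrate.quad(f, lo, hi, limit=200)
    return float(val)


# ---------------------------------------------------------------------------
# Registry of elicited and default priors
# ---------------------------------------------------------------------------

# Elicited parameters, one row per expert: (beta alpha, beta beta, t mu, t sigma, t nu)
_ELICITED = {
    1: (0.62, 22.44, 0.10, 0.12, 3),
    2: (5.32, 18.58, 0.55, 0.08, 3),
    3: (5.35, 15.69, 0.60, 0.11, 13),
    4: (10.70, 22.98, 0.59, 0.11, 3),
    5: (3.83, 8.76, 0.41, 0.12, 13),
    6: (8.65, 12.39, 0.31, 0.08, 9),
}


def expert_registry() -> dict[str, PriorSpec]:
    """The built-in prior registry.

    Returns the six elicited beta priors on rho, the six elicited truncated-t
    priors on delta, the default uniform(0, 1) prior on rho, the default
    positive-only Cauchy(0, sqrt(2)/2) prior on delta, and the two point nulls
    (rho = 0, delta = 0).
    """
    reg: dict[str, PriorSpec] = {}
    for k, (a, b, mu, sigma, nu) in _ELICITED.items():
        lab = f"Expert {k} (beta)"
        reg[lab] = PriorSpec("beta", {"alpha": a, "beta": b}, label=lab)
        lab = f"Expert {k} (t)"
        reg[lab] = PriorSpec(
            "t_truncated", {"mu": mu, "sigma": sigma, "nu": nu}, label=lab
        )
    reg["default (rho)"] = PriorSpec(
        "uniform", {"lower": 0.0, "upper": 1.0}, label="default (rho)"
    )
    reg["default (delta)"] = PriorSpec(
        "cauchy_truncated", {"scale": math.sqrt(2) / 2}, label="default (delta)"
    )
    reg["null (rho)"] = PriorSpec("point", {"value": 0.0}, label="null (rho)")
    reg["null (delta)"] = PriorSpec("point", {"value": 0.0}, label="null (delta)")
    return reg


def rho_priors(registry: Mapping[str, PriorSpec] | None = None) -> dict[str, PriorSpec]:
    """Registry subset usable for correlation tests (support within [0, 1])."""
    registry = expert_registry() if registry is None else registry
    out = {}
    for lab, spec in registry.items():
        lo, hi = spec.support
        if lo >= 0 and hi <= 1 and not spec.is_point:
            out[lab] = spec
    return out


def delta_priors(registry: Mapping[str, PriorSpec] | None = None) -> dict[str, PriorSpec]:
    """Registry subset usable for t-tests (half-line families on delta)."""
    registry = expert_registry() if registry is None else registry
    return {
        lab: s
        for lab, s in registry.items()
        if s.family in ("t_truncated", "normal_truncated", "cauchy_truncated")
    }


def registry_to_json(registry: Mapping[str, PriorSpec], path) -> None:
    with open(path, "w") as fh:
        json.dump([spec.to_dict() for spec in registry.values()], fh, indent=1)


def registry_from_json(path) -> dict[str, PriorSpec]:
    with open(path) as fh:
        items = json.load(fh)
    specs = [PriorSpec.from_dict(d) for d in items]
    return {s.label: s for s in specs}


# ---------------------------------------------------------------------------
# Elicitation grids and fitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ElicitationGrid:
    """A histogram-method elicitation: ten bins and the chips placed in each.

    The MATCH-style grid spans effect sizes 0 to 1 in ten equal bins with at
    most ten chips per bin. ``chips`` may carry expected (fractional) counts
    when a grid is generated deterministically; real elicitations are integer.
    """

    bin_edges: tuple[float, ...] = field(
        default_factory=lambda: tuple(np.linspace(0.0, 1.0, 11))
    )
    chips: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        if edges.size != 11 or np.any(np.diff(edges) <= 0):
            raise ValueError("bin_edges must be 11 strictly ascending values")
        chips = np.asarray(self.chips, dtype=float)
        if chips.size != 10 or np.any(chips < 0):
            raise ValueError("chips must be 10 non-negative counts")
        if np.any(chips > 10 + 1e-9):
            warnings.warn("chip count above the ten-per-bin grid maximum", UserWarning)
        object.__setattr__(self, "bin_edges", tuple(edges))
        object.__setattr__(self, "chips", tuple(chips))

    @property
    def total_chips(self) -> float:
        return float(np.sum(self.chips))

    @property
    def proportions(self) -> np.ndarray:
        if self.total_chips <= 0:
            raise ValueError("grid has no chips")
        return np.asarray(self.chips) / self.total_chips

    @classmethod
    def from_csv(cls, path) -> "ElicitationGrid":
        """Read a grid from a two-column CSV (bin_lower, chips)."""
        df = pd.read_csv(path)
        missing = {"bin_lower", "chips"} - set(df.columns)
        if missing:
            raise ValueError(f"grid CSV missing column(s): {sorted(missing)}")
        lowers = df["bin_lower"].to_numpy(dtype=float)
        width = np.diff(lowers)
        edges = np.concatenate([lowers, [lowers[-1] + (width[-1] if width.size else 0.1)]])
        return cls(bin_edges=tuple(edges), chips=tuple(df["chips"].to_numpy(dtype=float)))

    @classmethod
    def from_json(cls, path) -> "ElicitationGrid":
        with open(path) as fh:
            d = json.load(fh)
        return cls(bin_edges=tuple(d["bin_edges"]), chips=tuple(d["chips"]))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"bin_edges": list(self.bin_edges), "chips": list(self.chips)}, fh)


def _grid_bin_probs(spec: PriorSpec, edges: np.ndarray) -> np.ndarray:
    """Model bin probabilities: CDF differences renormalized to the grid range."""
    frozen = spec._frozen()
    cdf = frozen.cdf(edges)
    total = cdf[-1] - cdf[0]
    if total <= 0:
        return np.full(edges.size - 1, np.nan)
    return np.diff(cdf) / total


def _moment_start(grid: ElicitationGrid) -> tuple[float, float]:
    edges = np.asarray(grid.bin_edges)
    mids = 0.5 * (edges[:-1] + edges[1:])
    p = grid.proportions
    m = float(np.sum(p * mids))
    v = float(np.sum(p * (mids - m) ** 2))
    width = edges[-1] - edges[0]
    v = max(v, (0.05 * width) ** 2)  # floor: single-bin grids have zero spread
    return m, v


def fit_prior_to_grid(grid: ElicitationGrid, family: str) -> PriorSpec:
    """Fit a parametric prior to elicited chips by least squares on bin probabilities.

    Minimizes the sum of squared differences between the family's bin
    probabilities (CDF differences across the grid edges, renormalized to the
    grid range) and the chip proportions. Deterministic given the grid: the
    optimizer is bounded L-BFGS-B started from moment estimates.
    """
    if family not in ("beta", "t_truncated", "normal_truncated"):
        raise ValueError(f"unsupported fitting family {family!r}")
    if grid.total_chips <= 0:
        raise ValueError("cannot fit a prior to a grid with no chips")
    edges = np.asarray(grid.bin_edges)
    props = grid.proportions
    n_occupied = int(np.sum(np.asarray(grid.chips) > 0))
    n_params = {"beta": 2, "normal_truncated": 2, "t_truncated": 3}[family]
    if n_occupied < n_params:
        warnings.warn(
            f"{n_occupied} occupied bin(s) under-determine a {n_params}-parameter "
            f"{family} fit; returning best effort",
            UnderDeterminedFitWarning,
        )

    m, v = _moment_start(grid)
    width = edges[-1] - edges[0]

    if family == "beta":
        # method-of-moments start on the (assumed [0,1]) grid scale
        m01 = min(max((m - edges[0]) / width, 1e-3), 1 - 1e-3)
        common = max(m01 * (1 - m01) / v - 1, 0.1)
        x0 = np.log([max(m01 * common, 1e-2), max((1 - m01) * common, 1e-2)])
        bounds = [(math.log(1e-3), math.log(1e4))] * 2

        def make(x):
            a, b = np.exp(x)
            return PriorSpec("beta", {"alpha": a, "beta": b})

    elif family == "normal_truncated":
        x0 = np.array([m, math.log(math.sqrt(v))])
        bounds = [
            (edges[0] - width, edges[-1] + width),
            (math.log(1e-3 * width), math.log(10 * width)),
        ]

        def make(x):
            return PriorSpec("normal_truncated", {"mu": x[0], "sigma": math.exp(x[1])})

    else:  # t_truncated
        x0 = np.array([m, math.log(math.sqrt(v)), math.log(5.0)])
        bounds = [
            (edges[0] - width, edges[-1] + width),
            (math.log(1e-3 * width), math.log(10 * width)),
            (math.log(0.5), math.log(500.0)),
        ]

        def make(x):
            return PriorSpec(
                "t_truncated", {"mu": x[0], "sigma": math.exp(x[1]), "nu": math.exp(x[2])}
            )

    def objective(x):
        probs = _grid_bin_probs(make(x), edges)
        if not np.all(np.isfinite(probs)):
            return 1e6
        return float(np.sum((probs - props) ** 2))

    res = optimize.minimize(
        objective, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-12},
    )
    spec = make(res.x)
    return PriorSpec(spec.family, spec.params, label=f"fitted {family}")
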