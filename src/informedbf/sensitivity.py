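"""Prior-sensitivity analyses over a table of Bayes factors.

Three complementary views of how much the choice of prior matters across a
database of tests:

* **direction agreement** — how often two priors' Bayes factors fall on the
  same side of BF10 = 1;
* **evidence-category agreement** — how often they land in the same discrete
  evidence category (by default: strong H1 above 10, strong H0 below 1/10,
  inconclusive in between; a Jeffreys-style six-category scheme is available);
* **ratio summaries** — the distribution of pairwise Bayes-factor ratios,
  which are themselves Bayes factors comparing the two rival priors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .bayes_factors import BFResult

__all__ = [
    "EvidenceScheme",
    "AgreementMatrix",
    "categorize",
    "direction_agreement",
    "category_agreement",
    "pairwise_matrix",
    "ratio_summary",
]


@dataclass(frozen=True)
class EvidenceScheme:
    """A discretization of the Bayes factor into evidence categories.

    Edges are strictly increasing and partition (0, inf). Threshold crossings
    are strict on the strong side: a BF of exactly 10 (or 1/10) is *not* strong
    evidence.
    """

    name: str
    edges: tuple[float, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.edges) + 1:
            raise ValueError("need one more label than edges")
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("edges must be strictly increasing")

    @classmethod
    def strong_bounds(cls) -> "EvidenceScheme":
        """Strong H0 below 1/10, strong H1 above 10, inconclusive in between."""
        return cls("strong_bounds", (0.1, 10.0), ("strong_H0", "inconclusive", "strong_H1"))

    @classmethod
    def jeffreys(cls) -> "EvidenceScheme":
        """Six Jeffreys-style categories with edges 1/10, 1/3, 1, 3, 10."""
        return cls(
            "jeffreys",
            (1 / 10, 1 / 3, 1.0, 3.0, 10.0),
            (
                "strong H0",
                "moderate H0",
                "anecdotal H0",
                "anecdotal H1",
                "moderate H1",
                "strong H1",
            ),
        )

    @classmethod
    def by_name(cls, name: str) -> "EvidenceScheme":
        try:
            return {"strong_bounds": cls.strong_bounds, "jeffreys": cls.jeffreys}[name]()
        except KeyError:
            raise ValueError(f"unknown evidence scheme {name!r}") from None


def categorize(bf10, scheme: EvidenceScheme | None = None):
    """Evidence category label(s) for Bayes factor value(s).

    The outermost bins require strictly exceeding the outer edges (boundary
    values fall to the non-strong side); interior edges belong to the bin on
    the H0 side.
    """
    scheme = EvidenceScheme.strong_bounds() if scheme is None else scheme
    bf = np.asarray(bf10, dtype=float)
    if np.any(bf <= 0):
        raise ValueError("Bayes factors must be positive")
    # side="left": bf equal to an edge goes to the lower bin, making the upper
    # threshold strict; the lowest edge needs the symmetric strict rule.
    idx = np.searchsorted(scheme.edges, bf, side="left")
    idx = np.where(bf == scheme.edges[0], 1, idx)
    out = np.asarray(scheme.labels, dtype=object)[np.atleast_1d(idx)]
    return out if bf.ndim else out[0]


def _paired_bfs(
    bfs_a: Sequence[BFResult] | Sequence[float],
    bfs_b: Sequence[BFResult] | Sequence[float],
) -> tuple[np.ndarray, np.ndarray]:
    if len(bfs_a) != len(bfs_b):
        raise ValueError("sequences must have equal length")

    def values(seq):
        if len(seq) and isinstance(seq[0], BFResult):
            return np.array([x.bf10 for x in seq]), [x.study_id for x in seq]
        return np.asarray(seq, dtype=float), None

    a, ids_a = values(bfs_a)
    b, ids_b = values(bfs_b)
    if ids_a is not None and ids_b is not None and ids_a != ids_b:
        raise ValueError("study_id sequences are not aligned")
    return a, b


def direction_agreement(bfs_a, bfs_b) -> float:
    """Fraction of studies whose two Bayes factors fall strictly on the same side of 1.

    A BF exactly equal to 1 supports neither direction and counts as
    disagreement.
    """
    a, b = _paired_bfs(bfs_a, bfs_b)
    same = ((a > 1) & (b > 1)) | ((a < 1) & (b < 1))
    return float(np.mean(same))


def category_agreement(bfs_a, bfs_b, scheme: EvidenceScheme | None = None) -> float:
    """Fraction of studies whose two Bayes factors share the evidence category."""
    a, b = _paired_bfs(bfs_a, bfs_b)
    return float(np.mean(categorize(a, scheme) == categorize(b, scheme)))


@dataclass(frozen=True)
class AgreementMatrix:
    """Pairwise prior-vs-prior concordance rates (symmetric, unit diagonal)."""

    labels: tuple[str, ...]
    rates: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        r = np.asarray(self.rates, dtype=float)
        k = len(self.labels)
        if r.shape != (k, k):
            raise ValueError("rates must be k x k")
        if not np.allclose(r, r.T) or not np.allclose(np.diag(r), 1.0):
            raise ValueError("agreement matrix must be symmetric with unit diagonal")
        if np.any(r < 0) or np.any(r > 1):
            raise ValueError("rates must be in [0, 1]")
        object.__setattr__(self, "rates", r)

    def rate(self, label_a: str, label_b: str) -> float:
        i, j = self.labels.index(label_a), self.labels.index(label_b)
        return float(self.rates[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rates, index=list(self.labels), columns=list(self.labels))

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index_label="prior_label", float_format="%.12g")


def _bf_wide(bf_table: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long BF table to studies x priors, requiring a complete grid."""
    wide = bf_table.pivot(index="study_id", columns="prior_label", values="bf10")
    if wide.isna().any().any():
        missing = int(wide.isna().sum().sum())
        raise ValueError(f"BF table incomplete: {missing} missing study x prior cells")
    return wide


def pairwise_matrix(
    bf_table: pd.DataFrame,
    metric: str = "direction",
    scheme: EvidenceScheme | None = None,
) -> AgreementMatrix:
    """Agreement rates for all prior pairs over a long-format BF table.

    ``bf_table`` needs columns ``study_id``, ``prior_label`` and ``bf10`` (or
    ``log_bf10``), with a BF for every study under every prior.
    """
    if metric not in ("direction", "category"):
        raise ValueError(f"unknown metric {metric!r}")
    bf_table = bf_table.copy()
    if "bf10" not in bf_table.columns:
        bf_table["bf10"] = np.exp(bf_table["log_bf10"])
    wide = _bf_wide(bf_table)
    labels = tuple(wide.columns)
    k = len(labels)
    rates = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            a, b = wide.iloc[:, i].to_numpy(), wide.iloc[:, j].to_numpy()
            if metric == "direction":
                rates[i, j] = rates[j, i] = direction_agreement(a, b)
            else:
                rates[i, j] = rates[j, i] = category_agreement(a, b, scheme)
    return AgreementMatrix(labels=labels, rates=rates, metric=metric)


_RATIO_QUANTILES = (0.0, 0.025, 0.25, 0.5, 0.75, 0.975, 1.0)


def ratio_summary(bf_table: pd.DataFrame, return_ratios: bool = False):
    """Distribution summaries of pairwise Bayes-factor ratios.

    For each ordered pair of priors (a, b) the per-study ratio BF_a / BF_b is
    itself a Bayes factor comparing a's and b's models. Summaries include
    quantiles and the fraction of ratios inside [1/3, 3]; elementwise,
    ratio(a, b) = 1 / ratio(b, a).
    """
    bf_table = bf_table.copy()
    if "log_bf10" not in bf_table.columns:
        bf_table["log_bf10"] = np.log(bf_table["bf10"])
    if "bf10" not in bf_table.columns:
        bf_table["bf10"] = np.exp(bf_table["log_bf10"])
    wide_log = bf_table.pivot(index="study_id", columns="prior_label", values="log_bf10")
    if wide_log.isna().any().any():
        raise ValueError("BF table incomplete")
    labels = list(wide_log.columns)
    rows = []
    ratios: dict[tuple[str, str], np.ndarray] = {}
    for la in labels:
        for lb in labels:
            if la == lb:
                continue
            ratio = np.exp(wide_log[la].to_numpy() - wide_log[lb].to_numpy())
            ratios[(la, lb)] = ratio
            row = {"numerator": la, "denominator": lb}
            for q in _RATIO_QUANTILES:
                row[f"q{q:g}"] = float(np.quantile(ratio, q))
            row["frac_within_3fold"] = float(np.mean((ratio >= 1 / 3) & (ratio <= 3)))
            rows.append(row)
    summary = pd.DataFrame(rows)
    if return_ratios:
        return summary, ratios
    return summary
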