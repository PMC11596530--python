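"""Phase-II decomposition-efficiency computations.

Decomposition level is percent dry-mass loss of the applied cellulosic
substrate over incubation.  Compost chemistry panels (humidity, ash,
nitrate, water-soluble carbon, decomposition) are screened for redundancy by
pairwise Pearson correlation, and treatments are compared with a two-sided
Wilcoxon rank-sum test — exact by enumeration for small groups, a
tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import sparse, stats

DEFAULT_CORR_THRESHOLD = 0.7
#: Largest combined sample size for which the exact rank-sum null is
#: enumerated (C(12,6) = 924 assignments at worst).
EXACT_ENUMERATION_MAX_N = 12

#: Default Phase-II vessel composition: 10 g dry substrate + 1 g primer
#: inoculum (+30 mL water); decomposition is computed on the substrate basis.
DEFAULT_INITIAL_SUBSTRATE_G = 10.0
DEFAULT_PRIMER_G = 1.0


@dataclass(frozen=True)
class CompostMeasurement:
    """End-point measurements of one Phase-II compost vessel.

    ``treatment`` names the applied primer, or "no" for the uninoculated
    control.  ``auxiliary`` carries the chemistry panel (humidity %, ash %,
    nitrate, water-soluble carbon, ...).  A final mass above the initial mass
    is allowed (measurement noise) but flagged with a warning.
    """

    treatment: str
    substrate_type: str
    replicate: int
    initial_dry_mass: float
    final_dry_mass: float
    auxiliary: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.initial_dry_mass <= 0:
            raise ValueError("initial_dry_mass must be positive")
        if self.final_dry_mass < 0:
            raise ValueError("final_dry_mass must be non-negative")
        if self.final_dry_mass > self.initial_dry_mass:
            warnings.warn(
                f"mass gain in {self.treatment}/{self.substrate_type} r{self.replicate}: "
                f"{self.final_dry_mass} g > {self.initial_dry_mass} g",
                stacklevel=2,
            )


@dataclass(frozen=True)
class PairwiseTestResult:
    """Two-sided rank-sum comparison of two treatments.

    ``statistic`` is the rank-sum of group_a in the pooled ranking; stars
    follow the usual convention (** for p < 0.01, * for 0.01 ≤ p < 0.05).
    """

    group_a: str
    group_b: str
    statistic: float
    p_value: float
    stars: str

    def __post_init__(self) -> None:
        if not (0 < self.p_value <= 1):
            raise ValueError("p_value must lie in (0, 1]")
        if self.stars != significance_stars(self.p_value):
            raise ValueError("stars inconsistent with p_value")


def significance_stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def decomposition_level(m: CompostMeasurement) -> float:
    """Percent dry-mass loss: 100 × (initial − final) / initial, in [0, 100].

    Negative values (apparent mass gain) are clamped to 0 with a warning.
    """
    return mass_loss_percent(m.initial_dry_mass, m.final_dry_mass)


def mass_loss_percent(initial: float, final: float) -> float:
    if initial <= 0:
        raise ValueError("initial mass must be positive")
    level = 100.0 * (initial - final) / initial
    if level < 0:
        warnings.warn(f"apparent mass gain ({-level:.2f}%); clamping decomposition to 0")
        return 0.0
    return level


@dataclass(frozen=True)
class ParameterGroup:
    """A connected component of mutually correlated parameters."""

    members: tuple[str, ...]
    representative: str


def correlation_screen(
    measurements: pd.DataFrame,
    threshold: float = DEFAULT_CORR_THRESHOLD,
    representative_name: str = "decomposition",
) -> list[ParameterGroup]:
    """Group redundant compost parameters by pairwise Pearson correlation.

    ``measurements`` has samples as rows and parameters as columns.
    Parameters are linked when |r| > ``threshold``; connected components are
    reported with a chosen representative: the decomposition level when the
    component contains a column whose name includes ``representative_name``,
    otherwise the alphabetically first member.  Zero-variance parameters are
    excluded with a warning.
    """
    if measurements.shape[0] < 3:
        raise ValueError("correlation screen needs at least 3 samples")
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0, 1)")
    variances = measurements.var(axis=0)
    flat = variances[variances == 0].index.tolist()
    if flat:
        warnings.warn(f"excluding zero-variance parameters: {flat}")
    cols = [c for c in measurements.columns if c not in set(flat)]
    r = np.corrcoef(measurements[cols].to_numpy(dtype=float), rowvar=False)
    adj = np.abs(np.atleast_2d(r)) > threshold
    np.fill_diagonal(adj, False)
    n_comp, labels = sparse.csgraph.connected_components(
        sparse.csr_matrix(adj), directed=False
    )
    groups = []
    for comp in range(n_comp):
        members = tuple(sorted(c for c, l in zip(cols, labels) if l == comp))
        rep = next(
            (m for m in members if representative_name.lower() in m.lower()),
            members[0],
        )
        groups.append(ParameterGroup(members=members, representative=rep))
    return sorted(groups, key=lambda g: g.members)


def exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided rank-sum p-value by enumerating rank assignments.

    Pools the observations, ranks them (midranks for ties) and enumerates
    every C(n+m, n) assignment of ranks to the first group; the two-sided
    p-value is the fraction of assignments whose rank-sum deviates from the
    null mean at least as much as the observed one.  Returns (rank-sum, p).
    """
    n, m = len(x), len(y)
    ranks = stats.rankdata(np.concatenate([x, y])).tolist()
    w_obs = float(sum(ranks[:n]))
    mu = n * (n + m + 1) / 2.0
    dev_obs = abs(w_obs - mu)
    total = comb(n + m, n)
    hits = 0
    for idx in combinations(ranks, n):
        if abs(sum(idx) - mu) >= dev_obs - 1e-9:
            hits += 1
    return w_obs, hits / total


def _approx_rank_sum_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Tie-corrected normal approximation (via the Mann–Whitney U)."""
    n = len(x)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    w = float(res.statistic) + n * (n + 1) / 2.0  # U -> rank-sum of x
    return w, float(res.pvalue)


def rank_sum_pairwise(
    groups: dict[str, list[float] | np.ndarray],
    exact_max_n: int = EXACT_ENUMERATION_MAX_N,
    bh_adjust: bool = False,
) -> list[PairwiseTestResult]:
    """Two-sided Wilcoxon rank-sum test for every pair of treatments.

    Exact enumeration when the combined size is at most ``exact_max_n``,
    normal approximation with tie correction otherwise.  No multiplicity
    correction by default; ``bh_adjust`` applies Benjamini–Hochberg across
    the pairs.  Each group needs at least 3 observations.
    """
    for name, vals in groups.items():
        if len(vals) < 3:
            raise ValueError(f"group {name!r} has fewer than 3 observations")
    pairs = list(combinations(sorted(groups), 2))
    raw = []
    for a, b in pairs:
        x = np.asarray(groups[a], dtype=float)
        y = np.asarray(groups[b], dtype=float)
        if len(x) + len(y) <= exact_max_n:
            w, p = exact_rank_sum_p(x, y)
        else:
            w, p = _approx_rank_sum_p(x, y)
        raw.append((a, b, w, p))
    pvals = np.array([p for *_, p in raw])
    if bh_adjust and len(pvals):
        pvals = stats.false_discovery_control(pvals, method="bh")
    return [
        PairwiseTestResult(a, b, w, float(min(p, 1.0)), significance_stars(float(min(p, 1.0))))
        for (a, b, w, _), p in zip(raw, pvals)
    ]


def pairwise_results_frame(results: list[PairwiseTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group_a": r.group_a,
                "group_b": r.group_b,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "stars": r.stars,
            }
            for r in results
        ],
        columns=["group_a", "group_b", "statistic", "p_value", "stars"],
    )
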