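"""Frequencies, chi-square goodness of fit, tier clustering and diversity.

The integration hot-spot analysis reduces to a handful of categorical
statistics: frequency tables over labelled counts, Pearson chi-square tests
against a uniform (or supplied) expectation, an exact one-dimensional
minimum-variance partition of per-gene frequencies into tiers, and the
Shannon diversity index of categorical labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class FrequencyTable:
    categories: tuple[str, ...]
    counts: tuple[int, ...]
    n_total: int
    frequencies: tuple[float, ...]

    def frequency(self, category: str) -> float:
        return self.frequencies[self.categories.index(category)]


@dataclass(frozen=True)
class GofResult:
    statistic: float
    df: int
    p_value: float


@dataclass(frozen=True)
class Tier:
    members: tuple[str, ...]
    mean: float
    sem: float


@dataclass(frozen=True)
class TierAssignment:
    tiers: tuple[Tier, ...]  # ordered by increasing mean
    k: int

    @property
    def top(self) -> Tier:
        return self.tiers[-1]


def frequency_table(counts: dict[str, int]) -> FrequencyTable:
    """Relative frequencies of labelled non-negative counts (full precision)."""
    if any(c < 0 for c in counts.values()):
        raise ValueError("counts must be non-negative")
    total = sum(counts.values())
    if total == 0:
        raise ValueError("all counts are zero")
    cats = tuple(counts)
    vals = tuple(int(counts[c]) for c in cats)
    return FrequencyTable(
        categories=cats,
        counts=vals,
        n_total=total,
        frequencies=tuple(v / total for v in vals),
    )


def chi_square_sf(x: float, df: int) -> float:
    """Upper-tail probability of the chi-square distribution."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if x < 0:
        raise ValueError("statistic must be non-negative")
    return float(sps.chi2.sf(x, df))


def chi_square_gof(
    observed: dict[str, int] | list[int],
    expected: list[float] | None = None,
) -> GofResult:
    """Pearson chi-square goodness of fit, df = k - 1, no continuity correction.

    ``expected`` defaults to a discrete uniform expectation over the observed
    categories; it is rescaled to the observed total.
    """
    obs = np.asarray(
        list(observed.values()) if isinstance(observed, dict) else observed,
        dtype=float,
    )
    if len(obs) < 2:
        raise ValueError("need at least 2 categories")
    if expected is None:
        exp = np.full(len(obs), obs.sum() / len(obs))
    else:
        exp = np.asarray(expected, dtype=float)
        if len(exp) != len(obs):
            raise ValueError("expected and observed lengths differ")
        if np.any(exp <= 0):
            raise ValueError("expected counts must be positive")
        exp = exp * (obs.sum() / exp.sum())
    stat = float(((obs - exp) ** 2 / exp).sum())
    df = len(obs) - 1
    return GofResult(statistic=stat, df=df, p_value=chi_square_sf(stat, df))


def _sem(values: np.ndarray) -> float:
    if len(values) < 2:
        return 0.0
    return float(np.std(values, ddof=1) / np.sqrt(len(values)))


def tier_frequencies(per_gene_freqs: dict[str, float], k: int = 3) -> TierAssignment:
    """Exact 1-D minimum-variance partition of frequencies into k tiers.

    Values are sorted and split into k contiguous groups minimizing the total
    within-group sum of squared deviations (Fisher-Jenks dynamic program).
    The top tier (highest mean) contains the hot-spot candidates.
    """
    labels = sorted(per_gene_freqs, key=lambda g: (per_gene_freqs[g], g))
    x = np.asarray([per_gene_freqs[g] for g in labels], dtype=float)
    n = len(x)
    if k < 1 or k > n:
        raise ValueError(f"k={k} incompatible with {n} genes")
    csum = np.concatenate([[0.0], np.cumsum(x)])
    csq = np.concatenate([[0.0], np.cumsum(x * x)])

    def sse(i: int, j: int) -> float:
        # within-group sum of squares for x[i:j]
        s = csum[j] - csum[i]
        q = csq[j] - csq[i]
        m = j - i
        return q - s * s / m

    INF = float("inf")
    cost = np.full((k + 1, n + 1), INF)
    back = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for g in range(1, k + 1):
        for j in range(g, n + 1):
            best, arg = INF, g - 1
            for i in range(g - 1, j):
                c = cost[g - 1, i] + sse(i, j)
                if c < best - 1e-15:
                    best, arg = c, i
            cost[g, j] = best
            back[g, j] = arg
    bounds = [n]
    j = n
    for g in range(k, 0, -1):
        j = back[g, j]
        bounds.append(j)
    bounds.reverse()
    tiers = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        vals = x[a:b]
        tiers.append(
            Tier(members=tuple(labels[a:b]), mean=float(vals.mean()), sem=_sem(vals))
        )
    return TierAssignment(tiers=tuple(tiers), k=k)


def shannon_index(counts: dict[str, int]) -> float:
    """Shannon diversity H = -sum p_i ln p_i over categories with count > 0."""
    vals = np.asarray([c for c in counts.values() if c > 0], dtype=float)
    if vals.sum() == 0:
        raise ValueError("all counts are zero")
    p = vals / vals.sum()
    return float(-(p * np.log(p)).sum())
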