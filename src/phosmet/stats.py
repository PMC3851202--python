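"""Statistical procedures used throughout the pipeline.

All tests are implemented here rather than delegated to web services: the
pooled two-proportion Z-test, Pearson's chi-square test of independence, the
one-sided (upper-tail) hypergeometric test for over-representation with
Bonferroni correction, the log2 enrichment ratio, and the combinatorics of
multi-site PTM states. Tail probabilities come from scipy's distribution
CDFs; the test statistics themselves are computed locally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class ProportionComparison:
    """Pooled-variance Z-test for equality of two proportions."""

    x1: int
    n1: int
    x2: int
    n2: int
    z: float
    p_two_sided: float


def two_proportion_z(x1: int, n1: int, x2: int, n2: int) -> ProportionComparison:
    """Two-sided pooled-variance Z-test of H0: p1 == p2.

    With a degenerate pooled proportion (0 or 1) the data carry no evidence
    of a difference: z is defined as 0 and p as 1.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("both sample sizes must be >= 1")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts must satisfy 0 <= x <= n")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return ProportionComparison(x1, n1, x2, n2, z=0.0, p_two_sided=1.0)
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (x1 / n1 - x2 / n2) / se
    p = 2 * sps.norm.sf(abs(z))
    return ProportionComparison(x1, n1, x2, n2, z=z, p_two_sided=float(p))


@dataclass(frozen=True)
class ContingencyResult:
    """Pearson chi-square test of independence on an r x c table."""

    observed: tuple[tuple[float, ...], ...]
    statistic: float
    dof: int
    p: float


def chi_square_independence(table, yates: bool = False) -> ContingencyResult:
    """Pearson chi-square test of independence.

    Expected counts come from the row/column margins; no continuity
    correction by default (set ``yates`` for 2x2 tables with small counts).
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if (obs < 0).any():
        raise ValueError("counts must be nonnegative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("all-zero row or column margin")
    expected = np.outer(row, col) / obs.sum()
    diff = np.abs(obs - expected)
    if yates:
        diff = np.maximum(diff - 0.5, 0.0)
    statistic = float((diff ** 2 / expected).sum())
    dof = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(sps.chi2.sf(statistic, dof))
    return ContingencyResult(observed=tuple(map(tuple, obs)),
                             statistic=statistic, dof=dof, p=p)


def hypergeometric_upper(k: int, K: int, n: int, N: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N, K, n), summed exactly in log space.

    N is the background universe size, K the annotated background count, n
    the test-set size, k the annotated test-set count. This is the one-sided
    enrichment p-value: the chance of drawing at least k annotated items in n
    draws without replacement.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(f"invalid hypergeometric input k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    log_denom = _log_comb(N, n)
    upper = min(K, n)
    total = 0.0
    for j in range(k, upper + 1):
        if n - j > N - K:
            continue
        log_p = _log_comb(K, j) + _log_comb(N - K, n - j) - log_denom
        total += math.exp(log_p)
    return min(total, 1.0)


def _log_comb(a: int, b: int) -> float:
    return math.lgamma(a + 1) - math.lgamma(b + 1) - math.lgamma(a - b + 1)


def enrichment_z(k: int, K: int, n: int, N: int) -> float:
    """Normal-approximation z-score for a term's test-vs-background excess.

    Compares the term frequency in the test set (k/n) with the background
    frequency (K/N) using the pooled two-proportion form; used as the
    companion filter (z > 1.96) alongside the hypergeometric p.
    """
    return two_proportion_z(k, n, K, N).z


def bonferroni(p_values: list[float], m: int | None = None) -> list[float]:
    """Bonferroni-adjusted p-values: min(1, m * p).

    ``m`` defaults to the number of p-values and may be larger (when the
    family of tests exceeds the list reported).
    """
    if m is None:
        m = len(p_values)
    if m < len(p_values):
        raise ValueError("m must be >= number of p-values")
    for p in p_values:
        if not 0 <= p <= 1:
            raise ValueError(f"p-value {p} outside [0, 1]")
    return [min(1.0, m * p) for p in p_values]


def log2_enrichment_ratio(count_test: int, total_test: int,
                          count_bg: int, total_bg: int) -> float:
    """log2 of (test-set term proportion / background term proportion).

    Undefined (ValueError) when the term is absent from either set.
    """
    if count_test < 1 or count_bg < 1:
        raise ValueError("log2 ratio undefined for zero counts")
    return math.log2((count_test / total_test) / (count_bg / total_bg))


def percent_increase(log2_ratio: float) -> int:
    """Percent increase implied by a log2 ratio, to the nearest integer.

    A log2 ratio of 0.5 corresponds to a 41% increase in a term's relative
    frequency.
    """
    return round(100.0 * (2.0 ** log2_ratio - 1.0))


def ptm_state_count(n_sites: int, n_ptm_types: int = 1) -> int:
    """Number of distinct molecular species for n modifiable sites.

    Each site is either unmodified or carries one of ``n_ptm_types``
    modification types, giving (types + 1) ** sites species: 2^n for a single
    PTM type, 3^n when two types (e.g. phosphorylation and Met oxidation)
    can occur.
    """
    if n_sites < 0:
        raise ValueError("n_sites must be >= 0")
    if n_ptm_types < 1:
        raise ValueError("n_ptm_types must be >= 1")
    return (n_ptm_types + 1) ** n_sites
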