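"""Nonparametric two-sample tests and small exact statistics.

The Wilcoxon rank-sum test switches automatically between a full exact
enumeration over all C(n+m, n) group assignments (both groups of size
<= 10; midranks handle ties, so the exact path is a genuine permutation
test) and the tie-corrected normal approximation of the Mann-Whitney U
statistic for larger groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps

from .errors import ConfigError

ALTERNATIVES = ("two-sided", "greater", "less")


def significance_stars(p: float) -> str:
    """The conventional significance scale: * <0.05, ** <0.01, *** <0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class RankSumResult:
    statistic: float  #: rank sum of the first sample (midranks)
    p_value: float
    method: str  #: "exact" or "asymptotic"
    alternative: str
    n_x: int
    n_y: int


def rank_sum_test(
    x, y, alternative: str = "two-sided", exact_threshold: int = 10
) -> RankSumResult:
    """Wilcoxon rank-sum test of two independent samples.

    Exact enumeration is used when both groups have at most
    ``exact_threshold`` observations, otherwise the tie-corrected normal
    approximation (with continuity correction) via
    :func:`scipy.stats.mannwhitneyu`.
    """
    if alternative not in ALTERNATIVES:
        raise ConfigError(f"unknown alternative {alternative!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ConfigError("both samples must be non-empty")
    ranks = sps.rankdata(np.concatenate([x, y]))
    w_obs = float(ranks[: x.size].sum())
    if x.size <= exact_threshold and y.size <= exact_threshold:
        p = _exact_rank_sum_p(ranks, x.size, w_obs, alternative)
        return RankSumResult(w_obs, p, "exact", alternative, x.size, y.size)
    res = sps.mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
    return RankSumResult(w_obs, float(res.pvalue), "asymptotic", alternative, x.size, y.size)


def _exact_rank_sum_p(ranks: np.ndarray, n_x: int, w_obs: float, alternative: str) -> float:
    """Enumerate the rank-sum null over all assignments of n_x labels."""
    n = ranks.size
    total = comb(n, n_x)
    mean_w = n_x * ranks.mean()
    eps = 1e-9
    ge = le = extreme = 0
    for idx in combinations(range(n), n_x):
        w = ranks[list(idx)].sum()
        if w >= w_obs - eps:
            ge += 1
        if w <= w_obs + eps:
            le += 1
        if abs(w - mean_w) >= abs(w_obs - mean_w) - eps:
            extreme += 1
    if alternative == "greater":
        return ge / total
    if alternative == "less":
        return le / total
    return min(1.0, extreme / total)


@dataclass(frozen=True)
class KSResult:
    statistic: float
    p_value: float


def ks_test(x, y) -> KSResult:
    """Two-sample Kolmogorov-Smirnov test (two-sided)."""
    res = sps.ks_2samp(np.asarray(x, float), np.asarray(y, float))
    return KSResult(float(res.statistic), float(res.pvalue))


@dataclass(frozen=True)
class BinomialResult:
    k: int
    n: int
    p_expected: float
    p_value: float
    alternative: str


def binomial_test(k: int, n: int, p_expected: float,
                  alternative: str = "greater") -> BinomialResult:
    """Exact binomial test of ``k`` successes in ``n`` trials.

    Degenerate expectations are handled explicitly: p_expected = 1 makes
    every outcome certain (p = 1); p_expected = 0 makes any success
    impossible (p = 1 for k = 0, p = 0 otherwise, under 'greater').
    """
    if alternative not in ALTERNATIVES:
        raise ConfigError(f"unknown alternative {alternative!r}")
    if not 0 <= k <= n:
        raise ConfigError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 <= p_expected <= 1.0:
        raise ConfigError("p_expected must be in [0, 1]")
    if n == 0:
        return BinomialResult(k, n, p_expected, 1.0, alternative)
    res = sps.binomtest(k, n, p_expected, alternative=alternative)
    return BinomialResult(k, n, p_expected, float(res.pvalue), alternative)


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    p_value: float
    dof: int
    method: str  #: "chi2" or "fisher"
    table: tuple


def chi2_independence(table, yates: bool = False, fisher_fallback: bool = True) -> Chi2Result:
    """Pearson chi-squared test of independence on a contingency table.

    Yates correction is off by default. For 2x2 tables with any expected
    cell below 5 the Fisher exact test is used instead (reported in
    ``method``).
    """
    table = np.asarray(table, dtype=float)
    if table.min() < 0:
        raise ConfigError("contingency counts must be non-negative")
    chi2, p, dof, expected = sps.chi2_contingency(table, correction=yates)
    if fisher_fallback and table.shape == (2, 2) and expected.min() < 5:
        _, p_f = sps.fisher_exact(table)
        return Chi2Result(float(chi2), float(p_f), int(dof), "fisher",
                          tuple(map(tuple, table)))
    return Chi2Result(float(chi2), float(p), int(dof), "chi2", tuple(map(tuple, table)))
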