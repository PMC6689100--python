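"""Statistical primitives shared by every pipeline stage.

All tests return a :class:`TestResult`. Two-sided p-values for discrete
tests (Fisher exact, Hardy-Weinberg exact, beta-binomial) follow the
minimum-likelihood rule: the p-value is the total probability of all
outcomes whose null probability does not exceed that of the observed
outcome. This matches the convention of R's ``fisher.test``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.special import gammaln, ndtr, ndtri

__all__ = [
    "TestResult",
    "BetaBinomNull",
    "fisher_exact_2x2",
    "wilcoxon_rank_sum",
    "adjust_pvalues",
    "inverse_normal_transform",
    "hwe_exact_test",
    "betabinom_logpmf",
    "betabinom_loglik",
    "fit_betabinom",
    "betabinom_test",
]

# relative slack when comparing discrete outcome probabilities, so that
# outcomes tied with the observed one (up to rounding) are included
_REL_TIE_EPS = 1e-9


@dataclass
class TestResult:
    """Flat container for a single hypothesis test."""

    statistic: float
    p_value: float
    method: str
    estimate: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


@dataclass
class BetaBinomNull:
    """Fitted beta-binomial null for allelic read-count ratios.

    alpha and beta are the shape parameters of the latent Beta
    distribution of the per-read reference-allele probability.
    """

    alpha: float
    beta: float
    log_likelihood: float
    n_snps_used: int

    def __post_init__(self) -> None:
        if not (np.isfinite(self.alpha) and self.alpha > 0):
            raise ValueError("alpha must be finite and positive")
        if not (np.isfinite(self.beta) and self.beta > 0):
            raise ValueError("beta must be finite and positive")

    @property
    def mean_ratio(self) -> float:
        return self.alpha / (self.alpha + self.beta)


# ---------------------------------------------------------------------------
# Fisher exact test
# ---------------------------------------------------------------------------

def _log_hypergeom_pmf(x: np.ndarray, r1: int, r2: int, c1: int) -> np.ndarray:
    """log P(X = x) for the 2x2 table [[x, r1-x], [c1-x, r2-c1+x]]."""
    n = r1 + r2
    return (
        gammaln(r1 + 1) - gammaln(x + 1) - gammaln(r1 - x + 1)
        + gammaln(r2 + 1) - gammaln(c1 - x + 1) - gammaln(r2 - c1 + x + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    )


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> TestResult:
    """Two-sided Fisher exact test on a 2x2 contingency table.

    The p-value sums hypergeometric probabilities of all tables with the
    observed margins whose probability is <= the observed table's
    (minimum-likelihood rule). The odds ratio is the sample odds ratio
    (a*d)/(b*c), infinite when b*c = 0 and a*d > 0.
    """
    (a, b), (c, d) = table
    for v in (a, b, c, d):
        if v < 0 or v != int(v):
            raise ValueError("table entries must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    total = a + b + c + d
    if total == 0:
        raise ValueError("all-zero table")
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    support = np.arange(lo, hi + 1)
    logp = _log_hypergeom_pmf(support, r1, r2, c1)
    p_obs = np.exp(logp[a - lo])
    probs = np.exp(logp)
    p = float(probs[probs <= p_obs * (1 + _REL_TIE_EPS)].sum())
    p = min(1.0, p)
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    return TestResult(statistic=float(a), p_value=p, method="fisher_exact", estimate=odds)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum (Mann-Whitney)
# ---------------------------------------------------------------------------

def _mann_whitney_counts(n1: int, n2: int) -> np.ndarray:
    """Number of labelings giving each U value, U = 0..n1*n2 (no ties)."""
    # c[u] for (i, j): classic recurrence via generating function
    # (Gaussian binomial); build up one x-observation at a time.
    counts = np.zeros(n1 * n2 + 1, dtype=float)
    counts[0] = 1.0
    # polynomial product prod_{i=1..n1} (1 + q + ... + q^{n2}) adjusted:
    # U distribution = coefficients of Gaussian binomial [n1+n2 choose n1]_q
    poly = np.array([1.0])
    for i in range(1, n1 + 1):
        # multiply by (1 - q^{n2+i}) / (1 - q^{i})
        num = np.zeros(len(poly) + n2 + i, dtype=float)
        num[: len(poly)] += poly
        num[n2 + i : n2 + i + len(poly)] -= poly
        # divide by (1 - q^i): cumulative sum with stride i
        for j in range(i, len(num)):
            num[j] += num[j - i]
        # trim trailing zeros beyond degree i*n2
        poly = num[: i * n2 + 1]
    counts[: len(poly)] = poly
    return counts


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    mode: Literal["exact", "normal"] = "normal",
) -> TestResult:
    """Two-sided Wilcoxon rank-sum test.

    The statistic is the Mann-Whitney U for ``x``: the number of (x, y)
    pairs with x > y plus half the tied pairs. ``exact`` mode enumerates
    the permutation distribution (ties not supported, each group at most
    10); ``normal`` mode uses the tie-corrected normal approximation
    with a 0.5 continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    diff = x[:, None] - y[None, :]
    u = float((diff > 0).sum() + 0.5 * (diff == 0).sum())
    mu = n1 * n2 / 2.0
    if mode == "exact":
        if n1 > 10 or n2 > 10:
            raise ValueError("exact mode limited to 10 observations per group")
        pooled = np.concatenate([x, y])
        if np.unique(pooled).size < pooled.size:
            raise ValueError("ties present; use mode='normal'")
        counts = _mann_whitney_counts(n1, n2)
        dev = abs(u - mu)
        uu = np.arange(counts.size)
        p = counts[np.abs(uu - mu) >= dev - 1e-12].sum() / counts.sum()
        return TestResult(statistic=u, p_value=float(min(1.0, p)), method="wilcoxon_exact")
    if mode != "normal":
        raise ValueError(f"unknown mode {mode!r}")
    pooled = np.concatenate([x, y])
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float((tie_counts**3 - tie_counts).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return TestResult(statistic=u, p_value=1.0, method="wilcoxon_normal")
    z = (abs(u - mu) - 0.5) / math.sqrt(var)
    p = min(1.0, 2.0 * float(1.0 - ndtr(max(z, 0.0))))
    return TestResult(statistic=u, p_value=p, method="wilcoxon_normal")


# ---------------------------------------------------------------------------
# Multiple-testing adjustment
# ---------------------------------------------------------------------------

def adjust_pvalues(
    p: Sequence[float], method: Literal["bh", "bonferroni"] = "bh"
) -> np.ndarray:
    """Benjamini-Hochberg step-up or Bonferroni adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values outside [0, 1]")
    m = p.size
    if method == "bonferroni":
        return np.minimum(1.0, m * p)
    if method != "bh":
        raise ValueError(f"unknown method {method!r}")
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank down
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(1.0, adj)
    return out


# ---------------------------------------------------------------------------
# Inverse-normal transform
# ---------------------------------------------------------------------------

def _average_ranks(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(values.size, dtype=float)
    sorted_vals = values[order]
    i = 0
    while i < values.size:
        j = i
        while j + 1 < values.size and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def inverse_normal_transform(values: Sequence[float]) -> np.ndarray:
    """Rank-based inverse-normal transform.

    A value with average rank r among n maps to the standard-normal
    quantile of (r - 0.5)/n; ties share their average rank. Constant
    input is rejected (every rank would be tied, the output undefined).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    if np.all(values == values[0]):
        raise ValueError("constant input has no defined rank transform")
    ranks = _average_ranks(values)
    return ndtri((ranks - 0.5) / values.size)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> TestResult:
    """Exact conditional test of Hardy-Weinberg equilibrium.

    Conditions on the observed allele counts and sums, over all possible
    heterozygote counts of the correct parity, the probabilities of
    outcomes no more likely than the observed one (Levene's
    distribution, minimum-likelihood two-sided rule).
    """
    for v in (n_AA, n_Aa, n_aa):
        if v < 0 or v != int(v):
            raise ValueError("genotype counts must be non-negative integers")
    n_AA, n_Aa, n_aa = int(n_AA), int(n_Aa), int(n_aa)
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("empty sample")
    n_A = 2 * n_AA + n_Aa
    n_a = 2 * n_aa + n_Aa
    rare = min(n_A, n_a)
    hets = np.arange(rare % 2, rare + 1, 2)
    n_aa_h = (rare - hets) // 2
    n_AA_h = n - hets - n_aa_h
    logp = (
        gammaln(n + 1)
        - gammaln(n_AA_h + 1)
        - gammaln(hets + 1)
        - gammaln(n_aa_h + 1)
        + hets * math.log(2)
        + gammaln(n_A + 1)
        + gammaln(n_a + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[hets == n_Aa][0]
    p = float(probs[probs <= p_obs * (1 + _REL_TIE_EPS)].sum())
    return TestResult(statistic=float(n_Aa), p_value=min(1.0, p), method="hwe_exact")


# ---------------------------------------------------------------------------
# Beta-binomial
# ---------------------------------------------------------------------------

def betabinom_logpmf(
    k: np.ndarray | int, n: np.ndarray | int, alpha: float, beta: float
) -> np.ndarray:
    """log P(K = k | n, alpha, beta) for the beta-binomial distribution."""
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    return (
        gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
        + gammaln(k + alpha) + gammaln(n - k + beta) - gammaln(n + alpha + beta)
        - (gammaln(alpha) + gammaln(beta) - gammaln(alpha + beta))
    )


def betabinom_loglik(
    alpha: float, beta: float, counts: Sequence[tuple[int, int]]
) -> float:
    """Beta-binomial log-likelihood of (k, n) count pairs.

    Pairs with n = 0 contribute zero.
    """
    if not (alpha > 0 and beta > 0):
        raise ValueError("alpha and beta must be positive")
    k = np.array([c[0] for c in counts], dtype=float)
    n = np.array([c[1] for c in counts], dtype=float)
    if np.any(k < 0) or np.any(k > n):
        raise ValueError("counts must satisfy 0 <= k <= n")
    keep = n > 0
    if not keep.any():
        return 0.0
    return float(betabinom_logpmf(k[keep], n[keep], alpha, beta).sum())


_PARAM_CAP = 1e6


def _moment_start(k: np.ndarray, n: np.ndarray) -> tuple[float, float]:
    ratios = k / n
    m = float(ratios.mean())
    m = min(max(m, 1e-3), 1 - 1e-3)
    v = float(ratios.var())
    nbar = float(n.mean())
    # Var(k/n) ~ m(1-m)(1 + (n-1) rho) / n with rho = 1/(alpha+beta+1)
    if v <= 0 or nbar <= 1:
        rho = 0.05
    else:
        rho = (v * nbar / (m * (1 - m)) - 1.0) / (nbar - 1.0)
    rho = min(max(rho, 1e-4), 0.99)
    s = 1.0 / rho - 1.0
    return max(m * s, 1e-3), max((1 - m) * s, 1e-3)


def fit_betabinom(counts: Sequence[tuple[int, int]]) -> BetaBinomNull:
    """Maximum-likelihood beta-binomial fit to (k, n) count pairs.

    Optimizes on the log-parameter scale from a method-of-moments start;
    parameters are capped at 1e6 (beyond which the distribution is
    numerically binomial).
    """
    from scipy.optimize import minimize

    k = np.array([c[0] for c in counts], dtype=float)
    n = np.array([c[1] for c in counts], dtype=float)
    keep = n > 0
    k, n = k[keep], n[keep]
    if k.size < 10:
        raise ValueError("need at least 10 informative (n > 0) records")
    if np.any(k < 0) or np.any(k > n):
        raise ValueError("counts must satisfy 0 <= k <= n")

    def nll(logab: np.ndarray) -> float:
        a, b = np.exp(logab)
        return -float(betabinom_logpmf(k, n, a, b).sum())

    a0, b0 = _moment_start(k, n)
    bounds = [(math.log(1e-6), math.log(_PARAM_CAP))] * 2
    best = None
    for start in ([math.log(a0), math.log(b0)], [0.0, 0.0]):
        res = minimize(nll, np.array(start), method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    alpha, beta = np.exp(best.x)
    return BetaBinomNull(
        alpha=float(alpha),
        beta=float(beta),
        log_likelihood=-float(best.fun),
        n_snps_used=int(k.size),
    )


def betabinom_test(k: int, n: int, null: BetaBinomNull) -> TestResult:
    """Two-sided beta-binomial test of k reference reads out of n.

    Sums the null probabilities of all outcomes j in 0..n whose
    probability is <= that of the observed k (minimum-likelihood rule,
    mirroring the Fisher exact convention).
    """
    if n < 1 or k < 0 or k > n:
        raise ValueError("require 0 <= k <= n and n >= 1")
    j = np.arange(n + 1)
    logpmf = betabinom_logpmf(j, np.full(n + 1, n), null.alpha, null.beta)
    pmf = np.exp(logpmf - logpmf.max())
    pmf /= pmf.sum()
    p = float(pmf[pmf <= pmf[k] * (1 + _REL_TIE_EPS)].sum())
    ratio = k / n
    return TestResult(
        statistic=float(k),
        p_value=min(1.0, p),
        method="betabinom",
        estimate=ratio,
    )
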