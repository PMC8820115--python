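"""Nonparametric and binomial tests with exact small-sample modes.

Every statistic the rest of the package reports is computed here: the
continuity-corrected binomial z against a fair-coin null, the exact
two-tailed binomial, the one-sample Wilcoxon signed-rank test, the
Mann-Whitney U test, the Kruskal-Wallis H test, and Cohen's kappa for
inter-rater agreement.  The rank tests switch to exact enumeration of
the permutation null at small sample sizes and fall back on the usual
tie-corrected large-sample approximations above the thresholds.

Conventions (all documented, all two-tailed):

* ``binomial_z`` applies the +/-0.5 continuity correction and tests
  p = 0.5.
* ``binomial_exact`` doubles the smaller tail of Binomial(n, 1/2) and
  caps at 1 (tail-doubling, not the minimum-likelihood method).
* ``wilcoxon_signed_rank`` drops zero differences (classic convention,
  not Pratt) and reports the *signed rank sum* W = sum sign(d)*rank|d|,
  so W > 0 means the sample sits above the hypothesised location.
* ``mann_whitney_u`` reports U = min(U_a, U_b).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "Method",
    "TestResult",
    "binomial_z",
    "binomial_exact",
    "wilcoxon_signed_rank",
    "mann_whitney_u",
    "kruskal_wallis",
    "cohens_kappa",
    "InvalidInputError",
    "DegenerateInputError",
]

#: Largest post-drop sample size for which the signed-rank null is enumerated.
WILCOXON_EXACT_MAX_N = 20
#: Largest pooled size for which the Mann-Whitney null is enumerated.
MWU_EXACT_MAX_N = 14


class InvalidInputError(ValueError):
    """Raised when an input violates a test's preconditions."""


class DegenerateInputError(ValueError):
    """Raised when the data carry no information for the test (e.g. all
    values equal the hypothesised location)."""


class Method(str, Enum):
    BINOMIAL_Z = "binomial_z"
    BINOMIAL_EXACT = "binomial_exact"
    WILCOXON_SIGNED_RANK = "wilcoxon_signed_rank"
    MANN_WHITNEY = "mann_whitney"
    KRUSKAL_WALLIS = "kruskal_wallis"
    KAPPA = "kappa"


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test.

    Attributes
    ----------
    statistic
        The test's named statistic (z, W, U, H or kappa).
    p_value
        Two-tailed p-value in [0, 1] (chi-square upper tail for H).
    method
        Which test produced the result.
    n
        Sample-size descriptor (trials, post-drop pairs, pooled N, ...).
    exact
        True only when the exact enumeration path was taken.
    extra
        Method-specific extras (e.g. kappa standard error).
    """

    statistic: float
    p_value: float
    method: Method
    n: int
    exact: bool = False
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value out of [0,1]: {self.p_value}")

    def to_record(self) -> dict:
        rec = {
            "method": self.method.value,
            "statistic": float(self.statistic),
            "p_value": float(self.p_value),
            "n": int(self.n),
            "exact": bool(self.exact),
        }
        if self.extra:
            rec.update({k: float(v) for k, v in self.extra.items()})
        return rec


# ---------------------------------------------------------------------------
# binomial tests against a fair-coin null
# ---------------------------------------------------------------------------

def binomial_z(k: int, n: int) -> TestResult:
    """Continuity-corrected normal approximation to Binomial(n, 1/2).

    z = sign(k - n/2) * (|k - n/2| - 0.5) / sqrt(n/4); the statistic is 0
    when |k - n/2| <= 0.5.  Antisymmetric under k -> n - k.
    """
    k, n = int(k), int(n)
    if n < 1:
        raise InvalidInputError("binomial_z requires n >= 1")
    if not 0 <= k <= n:
        raise InvalidInputError(f"k={k} outside [0, n={n}]")
    d = k - n / 2.0
    z = math.copysign(max(abs(d) - 0.5, 0.0), d) / math.sqrt(n / 4.0)
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return TestResult(z, p, Method.BINOMIAL_Z, n)


def binomial_exact(k: int, n: int) -> TestResult:
    """Exact two-tailed binomial test of p = 0.5 by tail doubling."""
    k, n = int(k), int(n)
    if n < 1:
        raise InvalidInputError("binomial_exact requires n >= 1")
    if not 0 <= k <= n:
        raise InvalidInputError(f"k={k} outside [0, n={n}]")
    lower = sps.binom.cdf(k, n, 0.5)
    upper = sps.binom.sf(k - 1, n, 0.5)
    p = min(1.0, 2.0 * min(lower, upper))
    return TestResult(float(k), p, Method.BINOMIAL_EXACT, n, exact=True)


# ---------------------------------------------------------------------------
# Wilcoxon one-sample signed-rank test
# ---------------------------------------------------------------------------

def _signed_rank_exact_p(w_abs: float, ranks: np.ndarray) -> float:
    """P(|W| >= w_abs) under random signs, by dynamic programming over the
    distribution of the positive-rank sum T+ (integer ranks, no ties)."""
    r = ranks.astype(int)
    total = int(r.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for rank in r:
        shifted = np.zeros_like(counts)
        shifted[rank:] = counts[:-rank] if rank > 0 else counts
        counts = counts + shifted
    counts /= counts.sum()
    tplus = np.arange(total + 1)
    w = 2.0 * tplus - total  # W = T+ - T- = 2 T+ - sum(ranks)
    return float(counts[np.abs(w) >= w_abs - 1e-9].sum())


def wilcoxon_signed_rank(
    values: Sequence[float], mu0: float = 0.0
) -> TestResult:
    """One-sample Wilcoxon signed-rank test of location = ``mu0``.

    Zero differences are dropped; |differences| are midranked.  The
    reported statistic is the signed rank sum W = sum sign(d)*rank, so
    positive W means the values tend to lie above ``mu0``.  The p-value
    is exact (full sign enumeration via DP) when the post-drop n is at
    most ``WILCOXON_EXACT_MAX_N`` and there are no ties in |d|;
    otherwise a tie-corrected normal approximation is used.
    """
    d = np.asarray(values, dtype=float) - float(mu0)
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise DegenerateInputError("all values equal mu0; nothing to rank")
    ranks = sps.rankdata(np.abs(d))
    w = float(np.sum(np.sign(d) * ranks))
    has_ties = np.unique(np.abs(d)).size < n
    if n <= WILCOXON_EXACT_MAX_N and not has_ties:
        p = _signed_rank_exact_p(abs(w), ranks)
        return TestResult(w, min(p, 1.0), Method.WILCOXON_SIGNED_RANK, n, exact=True)
    # normal approximation on T+ with tie correction
    tplus = float(ranks[d > 0].sum())
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        raise DegenerateInputError("zero variance after tie correction")
    z = (tplus - mean) / math.sqrt(var)
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return TestResult(w, p, Method.WILCOXON_SIGNED_RANK, n, exact=False)


# ---------------------------------------------------------------------------
# Mann-Whitney U test
# ---------------------------------------------------------------------------

def _mwu_min_u(a_ranks_sum: float, n_a: int, n_b: int) -> float:
    u_a = n_a * n_b + n_a * (n_a + 1) / 2.0 - a_ranks_sum
    return min(u_a, n_a * n_b - u_a)


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sample Mann-Whitney test; reports U = min(U_a, U_b).

    Exact p by enumeration of all C(n_a+n_b, n_a) group labelings when
    the pooled size is at most ``MWU_EXACT_MAX_N``; otherwise normal
    approximation with tie correction and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n_a, n_b = a.size, b.size
    if n_a == 0 or n_b == 0:
        raise InvalidInputError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r_a = float(ranks[:n_a].sum())
    u = _mwu_min_u(r_a, n_a, n_b)
    n = n_a + n_b
    if n <= MWU_EXACT_MAX_N:
        count = 0
        total = 0
        idx = np.arange(n)
        for chosen in combinations(idx, n_a):
            total += 1
            rs = float(ranks[list(chosen)].sum())
            if _mwu_min_u(rs, n_a, n_b) <= u + 1e-9:
                count += 1
        return TestResult(u, count / total, Method.MANN_WHITNEY, n, exact=True)
    mean = n_a * n_b / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        raise DegenerateInputError("all pooled values identical")
    z = (u - mean + 0.5) / math.sqrt(var)  # U = min(.) <= mean, cc toward mean
    p = min(1.0, 2.0 * sps.norm.cdf(z))
    return TestResult(u, p, Method.MANN_WHITNEY, n, exact=False)


# ---------------------------------------------------------------------------
# Kruskal-Wallis H test
# ---------------------------------------------------------------------------

def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis rank test across >= 2 groups, tie-corrected,
    p from the chi-square approximation with (#groups - 1) df."""
    if len(groups) < 2:
        raise InvalidInputError("kruskal_wallis requires >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size == 0 for g in arrays):
        raise InvalidInputError("all groups must be non-empty")
    pooled = np.concatenate(arrays)
    if np.unique(pooled).size == 1:
        raise DegenerateInputError("all pooled values identical")
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    h = 0.0
    start = 0
    for g in arrays:
        rsum = float(ranks[start : start + g.size].sum())
        h += rsum**2 / g.size
        start += g.size
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)
    _, tie_counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - float(np.sum(tie_counts**3 - tie_counts)) / (
        n_total**3 - n_total
    )
    h /= correction
    df = len(arrays) - 1
    p = float(sps.chi2.sf(h, df))
    return TestResult(h, p, Method.KRUSKAL_WALLIS, n_total, extra={"df": df})


# ---------------------------------------------------------------------------
# Cohen's kappa
# ---------------------------------------------------------------------------

def cohens_kappa(confusion: Sequence[Sequence[int]]) -> TestResult:
    """Cohen's kappa for a square rater-1 x rater-2 count matrix.

    Returns kappa with its large-sample standard error (the Fleiss,
    Cohen & Everitt variance) in ``extra['se']`` and the raw percent
    agreement in ``extra['percent_agreement']``.
    """
    m = np.asarray(confusion, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise InvalidInputError("confusion matrix must be square")
    if np.any(m < 0):
        raise InvalidInputError("counts must be non-negative")
    n = m.sum()
    if n < 1:
        raise InvalidInputError("total count must be >= 1")
    p = m / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    po = float(np.trace(p))
    pe = float(np.sum(row * col))
    if pe >= 1.0 - 1e-12:
        raise DegenerateInputError("degenerate margins: Pe = 1")
    kappa = (po - pe) / (1.0 - pe)
    # Fleiss-Cohen-Everitt large-sample variance
    diag = np.diag(p)
    a = float(np.sum(diag * (1.0 - (row + col) * (1.0 - kappa)) ** 2))
    off = p.copy()
    np.fill_diagonal(off, 0.0)
    # cell (i, j) weight uses column margin of i and row margin of j
    b = (1.0 - kappa) ** 2 * float(
        np.sum(off * (col[:, np.newaxis] + row[np.newaxis, :]) ** 2)
    )
    c = (kappa - pe * (1.0 - kappa)) ** 2
    var = (a + b - c) / (n * (1.0 - pe) ** 2)
    se = math.sqrt(max(var, 0.0))
    zstat = kappa / se if se > 0 else math.inf
    pval = min(1.0, 2.0 * sps.norm.sf(abs(zstat))) if math.isfinite(zstat) else 0.0
    return TestResult(
        kappa,
        pval,
        Method.KAPPA,
        int(n),
        extra={"se": se, "percent_agreement": 100.0 * po},
    )
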