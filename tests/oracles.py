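"""Brute-force enumeration oracles, independent of the implementation.

Each oracle recomputes a null distribution by explicit enumeration
(sign assignments, group labelings, pmf summation) and is only usable
at tiny n — that is the point: the production code paths are checked
against these, never the other way round.
"""

from itertools import combinations, product
from math import comb

import numpy as np
from scipy.stats import rankdata


def binomial_exact_oracle(k: int, n: int) -> float:
    """Two-tailed tail-doubled binomial p by direct pmf summation."""
    pmf = [comb(n, i) * 0.5**n for i in range(n + 1)]
    lower = sum(pmf[: k + 1])
    upper = sum(pmf[k:])
    return min(1.0, 2.0 * min(lower, upper))


def signed_rank_oracle(values, mu0=0.0):
    """(W, two-tailed p) by enumerating all 2^n sign assignments.

    Tie-free inputs only (integer ranks)."""
    d = np.asarray(values, dtype=float) - mu0
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = float(np.sum(np.sign(d) * ranks))
    n = d.size
    count = 0
    for signs in product([-1.0, 1.0], repeat=n):
        w = float(np.dot(signs, ranks))
        if abs(w) >= abs(w_obs) - 1e-9:
            count += 1
    return w_obs, count / 2**n


def mwu_oracle(a, b):
    """(U=min(U_a,U_b), two-tailed p) by enumerating all group labelings."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)

    def min_u(rank_sum):
        u_a = n_a * n_b + n_a * (n_a + 1) / 2.0 - rank_sum
        return min(u_a, n_a * n_b - u_a)

    u_obs = min_u(float(ranks[:n_a].sum()))
    count = total = 0
    for chosen in combinations(range(n_a + n_b), n_a):
        total += 1
        if min_u(float(ranks[list(chosen)].sum())) <= u_obs + 1e-9:
            count += 1
    return u_obs, count / total


def pairwise_u_oracle(a, b):
    """U = min over directions of the direct pairwise-comparison count,
    counting ties as 1/2."""
    a = np.asarray(a, dtype=float)[:, None]
    b = np.asarray(b, dtype=float)[None, :]
    u_ab = float(np.sum(a < b) + 0.5 * np.sum(a == b))
    u_ba = float(np.sum(a > b) + 0.5 * np.sum(a == b))
    return min(u_ab, u_ba)
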