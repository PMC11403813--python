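"""Independent oracles used by the tests.

These deliberately avoid the code paths (and where possible the library
calls) they are used to check.
"""

from __future__ import annotations

import math
from itertools import combinations, product

import numpy as np
from scipy.integrate import quad


def chi2_sf_quad(stat: float, df: int) -> float:
    """Upper-tail chi-square probability by numerical integration of the
    density x^(k-1) e^(-x/2) / (2^k Gamma(k)), k = df/2."""
    k = df / 2.0
    def dens(x):
        return x ** (k - 1) * math.exp(-x / 2) / (2**k * math.gamma(k))
    val, _ = quad(dens, stat, math.inf)
    return val


def fisher_quad(pvals) -> float:
    stat = -2.0 * sum(math.log(p) for p in pvals)
    return chi2_sf_quad(stat, 2 * len(pvals))


def pagerank_linear(A: np.ndarray, damping: float = 0.85) -> np.ndarray:
    """PageRank by a dense linear solve of the fixed point.

    Dangling rows are replaced by uniform rows; then
    v = damping P^T v + (1-damping)/n, solved directly.
    """
    n = A.shape[0]
    P = np.array(A, dtype=float)
    out = P.sum(axis=1)
    for i in range(n):
        if out[i] == 0:
            P[i, :] = 1.0 / n
        else:
            P[i, :] /= out[i]
    v = np.linalg.solve(np.eye(n) - damping * P.T, np.full(n, (1 - damping) / n))
    return v / v.sum()


def max_clique_brute(n: int, edges: set[frozenset[int]]) -> set[int]:
    """Exhaustive maximum clique over all subsets of an n-node graph."""
    best: tuple[int, tuple[int, ...]] = (0, ())
    for size in range(n, 0, -1):
        found = []
        for sub in combinations(range(n), size):
            if all(frozenset((a, b)) in edges for a, b in combinations(sub, 2)):
                found.append(sub)
        if found:
            return set(min(found))
    return set()


def signed_rank_greater_brute(diff: np.ndarray) -> float:
    """Exact one-sided signed-rank p by enumerating every sign assignment."""
    from scipy.stats import rankdata

    d = np.asarray(diff, float)
    d = d[d != 0]
    n = d.size
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    count = 0
    for signs in product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if w >= w_obs - 1e-12:
            count += 1
    return count / 2**n
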