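"""Independent brute-force oracles used by unit and acceptance tests.

Everything here is deliberately naive — explicit enumeration with exact
rational arithmetic — and shares no code path with the package.
"""

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np


def hypergeom_pmf(N, K, n):
    """Exact pmf over the full support, by direct counting."""
    denom = comb(N, n)
    return {k: Fraction(comb(K, k) * comb(N - K, n - k), denom)
            for k in range(max(0, n - (N - K)), min(K, n) + 1)}


def hypergeom_tails(k, n, K, N):
    pmf = hypergeom_pmf(N, K, n)
    upper = sum(p for kk, p in pmf.items() if kk >= k)
    lower = sum(p for kk, p in pmf.items() if kk <= k)
    return float(upper), float(lower)


def mann_whitney_exact(x, y):
    """Two-sided exact Mann-Whitney p by enumerating rank assignments.

    Assumes no ties. Returns (U of x, p)."""
    pooled = sorted(list(x) + list(y))
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n, m = len(x), len(y)
    u_obs = sum(ranks[v] for v in x) - n * (n + 1) // 2
    us = []
    for combo in combinations(range(1, n + m + 1), n):
        us.append(sum(combo) - n * (n + 1) // 2)
    us = np.array(us)
    total = len(us)
    p = 2 * min((us <= u_obs).sum(), (us >= u_obs).sum()) / total
    return u_obs, min(1.0, p)


def tom_triple_loop(A):
    """Topological overlap by explicit triple loop."""
    n = A.shape[0]
    k = A.sum(axis=1)
    T = np.zeros_like(A, dtype=float)
    for i in range(n):
        for j in range(n):
            if i == j:
                T[i, j] = 1.0
                continue
            shared = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
            T[i, j] = (shared + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
    return T


def wto_triple_loop(A):
    """Signed weighted topological overlap by explicit triple loop."""
    n = A.shape[0]
    k = np.abs(A).sum(axis=1)
    W = np.zeros_like(A, dtype=float)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
            W[i, j] = (A[i, j] + shared) / (min(k[i], k[j]) + 1 - abs(A[i, j]))
    return W
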