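"""Independent brute-force oracles used only by the test suite.

Everything here is written from first principles (explicit mid-ranks,
exhaustive simple-path enumeration, stdlib normal quantiles) and deliberately
shares no code path with the package implementation it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

# -- rank correlation -------------------------------------------------------


def midrank(v) -> np.ndarray:
    """Average (mid) ranks, 1-based, computed by explicit tie grouping."""
    v = np.asarray(v, dtype=float)
    n = len(v)
    order = np.argsort(v, kind="stable")
    ranks = np.empty(n)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_oracle(x, y) -> float:
    """Pearson correlation of mid-ranks, written out longhand."""
    rx = midrank(x)
    ry = midrank(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / math.sqrt((rx**2).sum() * (ry**2).sum()))


def spearman_matrix_oracle(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    R = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            R[i, j] = R[j, i] = spearman_oracle(X[:, i], X[:, j])
    return R


# -- shortest paths and centrality ------------------------------------------


def enumerate_geodesics(A, rel_tol: float = 1e-9):
    """All-pairs shortest paths by exhaustive simple-path enumeration.

    ``A`` is a symmetric weight matrix; edge length is 1/|w|, no edge for
    w = 0.  Returns (distance matrix, geodesic-count matrix, dict of
    geodesic node-tuples per unordered pair).  Feasible only for small n.
    """
    A = np.abs(np.asarray(A, dtype=float))
    n = A.shape[0]
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    counts = np.zeros((n, n))
    np.fill_diagonal(counts, 1.0)
    geodesics: dict[tuple[int, int], list[tuple[int, ...]]] = {}
    for s in range(n):
        for t in range(s + 1, n):
            inter = [v for v in range(n) if v != s and v != t]
            found: list[tuple[float, tuple[int, ...]]] = []
            for k in range(len(inter) + 1):
                for perm in itertools.permutations(inter, k):
                    path = (s, *perm, t)
                    d = 0.0
                    ok = True
                    for u, v in zip(path, path[1:]):
                        if A[u, v] <= 0.0:
                            ok = False
                            break
                        d += 1.0 / A[u, v]
                    if ok:
                        found.append((d, path))
            if not found:
                geodesics[(s, t)] = []
                continue
            best = min(d for d, _ in found)
            tied = [p for d, p in found if d <= best * (1.0 + rel_tol) + rel_tol]
            D[s, t] = D[t, s] = best
            counts[s, t] = counts[t, s] = len(tied)
            geodesics[(s, t)] = tied
    return D, counts, geodesics


def strength_oracle(A) -> np.ndarray:
    B = np.abs(np.asarray(A, dtype=float)).copy()
    np.fill_diagonal(B, 0.0)
    return B.sum(axis=1)


def closeness_oracle(D) -> np.ndarray:
    """Component-penalized closeness from a distance matrix."""
    n = D.shape[0]
    out = np.zeros(n)
    for v in range(n):
        finite = [D[v, u] for u in range(n) if u != v and math.isfinite(D[v, u])]
        r = len(finite)
        if r > 0 and sum(finite) > 0:
            out[v] = (r / sum(finite)) * (r / (n - 1))
    return out


def betweenness_oracle(A, geodesics=None) -> np.ndarray:
    """Normalized betweenness with fractional credit over tied geodesics."""
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    if geodesics is None:
        _, _, geodesics = enumerate_geodesics(A)
    bet = np.zeros(n)
    for (s, t), paths in geodesics.items():
        if not paths:
            continue
        sigma = len(paths)
        for v in range(n):
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p[1:-1])
            bet[v] += through / sigma
    return bet / ((n - 1) * (n - 2) / 2.0)


def random_weighted_graph(rng: np.random.Generator, n: int) -> np.ndarray:
    """Seeded random family: each edge present w.p. 0.6, |w| in [0.1, 1]."""
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.6:
                w = rng.uniform(0.1, 1.0) * rng.choice([-1.0, 1.0])
                W[i, j] = W[j, i] = w
    np.fill_diagonal(W, 1.0)
    return W
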