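"""Independent brute-force oracles used by the test suite.

Every function here recomputes a quantity by the most literal method
available (exhaustive enumeration, triple loops, textbook formulas) and is
deliberately kept independent of the implementation paths it checks.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import numpy as np


def visible_bruteforce(x, i: int, j: int) -> bool:
    """Literal O(N) check of the visibility inequality for one pair."""
    x = np.asarray(x, dtype=float)
    if j == i + 1:
        return True
    for n in range(i + 1, j):
        if not x[n] < x[j] + (x[j] - x[i]) * (n - j) / (j - i):
            return False
    return True


def adjacency_bruteforce(x) -> np.ndarray:
    """O(N^3) assembly of the weighted adjacency from pairwise checks."""
    x = np.asarray(x, dtype=float)
    n = x.size
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if visible_bruteforce(x, i, j):
                W[i, j] = W[j, i] = abs(x[i] - x[j]) + 1.0
    return W


def floyd_warshall(W: np.ndarray) -> np.ndarray:
    """All-pairs relaxation with edge length W_ij."""
    n = W.shape[0]
    d = np.where(W > 0, W, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def clustering_pair_enumeration(W: np.ndarray, weighted: bool) -> np.ndarray:
    """C_i by explicit enumeration of all neighbor pairs of each node."""
    n = W.shape[0]
    C = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if W[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        L_i = 0.0
        for a, b in combinations(nbrs, 2):
            if W[a, b] > 0:
                L_i += W[a, b] if weighted else 1.0
        C[i] = 2.0 * L_i / (k * (k - 1))
    return C


def transitivity_triple_loop(W: np.ndarray) -> float:
    """T by counting triangles and connected triples with explicit loops."""
    n = W.shape[0]
    A = W > 0
    triangles = 0
    for i, j, k in combinations(range(n), 3):
        if A[i, j] and A[j, k] and A[i, k]:
            triangles += 1
    triples = 0
    for i in range(n):
        k_i = int(A[i].sum())
        triples += k_i * (k_i - 1) // 2
    if triples == 0:
        return float("nan")
    return 3.0 * triangles / triples


def assortativity_direct(W: np.ndarray) -> float:
    """Direct evaluation of the four sums in the assortativity ratio."""
    n = W.shape[0]
    k = np.array([np.count_nonzero(W[i]) for i in range(n)], dtype=float)
    s1 = sum(k)
    s2 = sum(v ** 2 for v in k)
    s3 = sum(v ** 3 for v in k)
    se = 0.0
    for i in range(n):
        for j in range(n):
            se += W[i, j] * k[i] * k[j]
    denom = s1 * s3 - s2 ** 2
    if denom == 0:
        return float("nan")
    return (s1 * se - s2 ** 2) / denom


def betweenness_path_enumeration(W: np.ndarray, rtol: float = 1e-9) -> np.ndarray:
    """B_u by enumerating every simple path between every unordered pair.

    Counts all paths whose total weight is within ``rtol`` of the minimum,
    matching the tie convention of the implementation under test.  Feasible
    only for small graphs (N <= 8 or so).
    """
    n = W.shape[0]
    G = nx.from_numpy_array(W)
    B = np.zeros(n)
    for i, j in combinations(range(n), 2):
        paths = list(nx.all_simple_paths(G, i, j))
        weights = [sum(W[a, b] for a, b in zip(p, p[1:])) for p in paths]
        wmin = min(weights)
        shortest = [p for p, w in zip(paths, weights)
                    if w <= wmin * (1 + rtol)]
        for u in range(n):
            if u in (i, j):
                continue
            through = sum(1 for p in shortest if u in p)
            B[u] += through / len(shortest)
    return B


def anova_f_sum_of_squares(groups) -> float:
    """One-way fixed-effects F from the textbook decomposition."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    n = sum(g.size for g in groups)
    grand = np.concatenate(groups).mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    return (ssb / (k - 1)) / (ssw / (n - k))


def random_epoch(rng: np.random.Generator, n: int) -> np.ndarray:
    """A random peak-normalized amplitude sequence."""
    x = rng.uniform(0.0, 1.0, n)
    x[rng.integers(n)] = 1.0
    return x
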