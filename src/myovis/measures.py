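"""The thirteen network measurements computed from a weighted adjacency matrix.

Scalar measures
---------------
==========  =====================================================
AD          average degree, 2L/N
ACC         average clustering coefficient (weighted by default)
T           transitivity, 3 * triangles / connected triples
As          degree assortativity with weighted S_e
Den         link density, 2L / (N(N-1))
CPD         central point dominance from betweenness centrality
CC          mean closeness centrality, N / sum_j d_ij
ASP         average shortest path length
E           global efficiency (mean inverse path length)
D           network diameter, max d_ij
AW          average weight, (sum_ij W_ij) / N
skewness    third standardized moment of all N^2 matrix elements
kurtosis    fourth standardized moment of all N^2 matrix elements
==========  =====================================================

Degenerate cases (regular-graph assortativity, zero-variance weight
moments, a triangle-free transitivity denominator) return NaN and emit an
:class:`~myovis.errors.UndefinedMeasureWarning` — never a silent zero.

Weight moments use all N^2 matrix elements (zeros and diagonal included)
and the population standard deviation; this is the convention under which
the mean of the worked reference network equals its total weight divided by
N^2.
"""

from __future__ import annotations

import heapq
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import InvariantViolationError, UndefinedMeasureWarning

MEASURE_NAMES = ["AD", "ACC", "T", "As", "Den", "CPD", "CC", "ASP", "E", "D",
                 "AW", "skewness", "kurtosis"]

#: relative tolerance treating two shortest-path lengths as tied
PATH_TIE_RTOL = 1e-9


def _as_matrix(W) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise InvariantViolationError("adjacency matrix must be square")
    if not np.allclose(W, W.T):
        raise InvariantViolationError("adjacency matrix must be symmetric")
    return W


def _undefined(name: str, reason: str) -> float:
    warnings.warn(f"{name} undefined: {reason}", UndefinedMeasureWarning,
                  stacklevel=3)
    return float("nan")


def degree_vector(W) -> np.ndarray:
    """k_i = number of links incident to node i."""
    W = _as_matrix(W)
    return np.count_nonzero(W, axis=1).astype(int)


def n_links(W) -> int:
    """L = half the number of nonzero off-diagonal entries."""
    return int(degree_vector(W).sum()) // 2


def average_degree(W) -> float:
    """AD = 2L / N."""
    W = _as_matrix(W)
    return 2.0 * n_links(W) / W.shape[0]


def density(W) -> float:
    """Den = 2L / (N(N-1))."""
    W = _as_matrix(W)
    n = W.shape[0]
    if n < 2:
        raise InvariantViolationError("density needs N >= 2")
    return 2.0 * n_links(W) / (n * (n - 1))


def average_clustering(W, weighted: bool = True) -> tuple[np.ndarray, float]:
    """Per-node clustering C_i = 2 L_i / (k_i (k_i - 1)) and its mean ACC.

    L_i counts the links among the neighbors of i — as a weight sum in
    weighted mode (the default; per-node values may then exceed 1), as a
    plain count otherwise.  Nodes with fewer than two neighbors get C_i = 0.
    """
    W = _as_matrix(W)
    n = W.shape[0]
    k = degree_vector(W)
    A = W > 0
    C = np.zeros(n)
    for i in range(n):
        if k[i] < 2:
            continue
        nbrs = np.nonzero(A[i])[0]
        sub = W[np.ix_(nbrs, nbrs)]
        if weighted:
            L_i = np.triu(sub, k=1).sum()
        else:
            L_i = np.count_nonzero(np.triu(sub, k=1))
        C[i] = 2.0 * L_i / (k[i] * (k[i] - 1))
    return C, float(C.mean())


def transitivity(W) -> float:
    """T = 3 * triangles / connected triples, on the binarized graph."""
    W = _as_matrix(W)
    A = (W > 0).astype(float)
    k = A.sum(axis=1)
    triples = float((k * (k - 1)).sum() / 2.0)
    if triples == 0:
        return _undefined("transitivity", "graph has no connected triples")
    triangles = float(np.trace(A @ A @ A)) / 6.0
    return 3.0 * triangles / triples


def transitivity_from_counts(triangle_term: float, triples: float) -> float:
    """Ratio form of transitivity for an externally supplied numerator.

    The numerator is taken as already complete (no factor of 3 applied);
    used to check printed worked-example arithmetic.
    """
    if triples == 0:
        return _undefined("transitivity", "zero triples")
    return float(triangle_term) / float(triples)


def assortativity(W) -> float:
    """Degree assortativity As = (S1*Se - S2^2) / (S1*S3 - S2^2).

    S_m are degree power sums; S_e = sum_ij W_ij k_i k_j over all ordered
    pairs, so link weights enter the numerator.  Regular graphs (all degrees
    equal) have a zero denominator and return NaN.
    """
    W = _as_matrix(W)
    k = degree_vector(W).astype(float)
    s1, s2, s3 = k.sum(), (k ** 2).sum(), (k ** 3).sum()
    se = float(k @ W @ k)
    denom = s1 * s3 - s2 ** 2
    if np.isclose(denom, 0.0):
        return _undefined("assortativity", "regular graph (zero denominator)")
    return (s1 * se - s2 ** 2) / denom


def distance_matrix(W, mode: str = "shortest_path") -> np.ndarray:
    """Pairwise path lengths d_ij.

    ``shortest_path``: minimum total edge weight over all paths (edge length
    = W_ij); always finite because the adjacency chain keeps the graph
    connected.  ``direct``: d_ij = W_ij, zero where no link.
    """
    W = _as_matrix(W)
    if mode == "direct":
        return W.copy()
    if mode != "shortest_path":
        raise ValueError(f"unknown distance mode {mode!r}")
    return _csgraph_shortest_path(csr_matrix(W), method="D", directed=False)


def path_summaries(d: np.ndarray) -> tuple[float, float, float]:
    """(ASP, E, D) from a distance matrix.

    ASP averages all off-diagonal entries over N(N-1) (zeros contribute
    zero in direct mode); E averages reciprocals of the positive
    off-diagonal entries over the same N(N-1); D is the largest entry.
    """
    d = _as_matrix(d)
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    vals = d[off]
    asp = float(vals.sum() / (n * (n - 1)))
    pos = vals[vals > 0]
    if pos.size == 0:
        e = _undefined("global efficiency", "all off-diagonal distances zero")
    else:
        e = float((1.0 / pos).sum() / (n * (n - 1)))
    return asp, e, float(vals.max())


def betweenness_cpd(W, d_mode: str = "shortest_path") -> tuple[np.ndarray, float]:
    """Betweenness centrality B_u and central point dominance.

    B_u = sum over unordered pairs {i, j} (u excluded) of the fraction of
    minimum-weight paths between i and j passing through u; all distinct
    minimum-weight paths are counted, with path-length ties resolved at a
    1e-9 relative tolerance.  CPD = sum_i (B_max - B_i) / (N - 1).

    In ``direct`` distance mode no path has interior nodes, so B_u = 0.
    """
    W = _as_matrix(W)
    n = W.shape[0]
    if d_mode == "direct":
        B = np.zeros(n)
    elif d_mode == "shortest_path":
        B = _brandes_betweenness(W)
    else:
        raise ValueError(f"unknown distance mode {d_mode!r}")
    cpd = float((B.max() - B).sum() / (n - 1)) if n > 1 else 0.0
    return B, cpd


def _brandes_betweenness(W: np.ndarray, rtol: float = PATH_TIE_RTOL) -> np.ndarray:
    """Brandes' accumulation with a tolerance-aware Dijkstra.

    Two tentative path lengths within ``rtol`` (relative) are treated as
    tied, so all minimum-weight paths are counted even when edge-weight sums
    differ only by floating-point rounding.
    """
    n = W.shape[0]
    adj = [np.nonzero(W[v])[0] for v in range(n)]
    B = np.zeros(n)
    for s in range(n):
        dist = np.full(n, np.inf)
        sigma = np.zeros(n)
        preds: list[list[int]] = [[] for _ in range(n)]
        dist[s] = 0.0
        sigma[s] = 1.0
        done = np.zeros(n, dtype=bool)
        order: list[int] = []
        heap: list[tuple[float, int]] = [(0.0, s)]
        while heap:
            dv, v = heapq.heappop(heap)
            if done[v]:
                continue
            done[v] = True
            order.append(v)
            for w in adj[v]:
                if done[w]:
                    continue
                nd = dist[v] + W[v, w]
                tol = rtol * max(1.0, abs(dist[w])) if np.isfinite(dist[w]) else 0.0
                if nd < dist[w] - tol:
                    dist[w] = nd
                    sigma[w] = sigma[v]
                    preds[w] = [v]
                    heapq.heappush(heap, (nd, w))
                elif abs(nd - dist[w]) <= tol:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        delta = np.zeros(n)
        for w in reversed(order):
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                B[w] += delta[w]
    return B / 2.0          # each unordered pair was visited from both ends


def closeness(d: np.ndarray) -> np.ndarray:
    """CC_i = N / sum_j d_ij for each node."""
    d = _as_matrix(d)
    n = d.shape[0]
    row = d.sum(axis=1)
    cc = np.full(n, np.nan)
    bad = row <= 0
    if bad.any():
        _undefined("closeness", f"{int(bad.sum())} node(s) with zero distance sum")
    cc[~bad] = n / row[~bad]
    return cc


def weight_moments(W) -> tuple[float, float, float, float, float]:
    """(AW, mu, s, skewness, kurtosis) over all N^2 matrix elements.

    AW is the total weight divided by N; mu and s are the mean and
    population standard deviation of the flattened matrix; skewness and
    kurtosis are the standardized third and fourth central moments (kurtosis
    is not excess-corrected).
    """
    W = _as_matrix(W)
    flat = W.ravel()
    n = W.shape[0]
    aw = float(flat.sum() / n)
    mu = float(flat.mean())
    s = float(flat.std())
    if s == 0:
        skew = _undefined("skewness", "all matrix elements equal")
        kurt = _undefined("kurtosis", "all matrix elements equal")
    else:
        skew = float(stats.skew(flat))
        kurt = float(stats.kurtosis(flat, fisher=False))
    return aw, mu, s, skew, kurt


def compute_all(W, clustering_weighted: bool = True,
                distance_mode: str = "shortest_path",
                measures: list[str] | None = None) -> dict[str, float]:
    """Assemble the requested scalar measures (all thirteen by default).

    Undefined measures carry NaN plus a warning, never a silent zero.
    Restricting ``measures`` skips the expensive all-pairs computations when
    no path-based measure is requested.
    """
    W = _as_matrix(W)
    names = MEASURE_NAMES if measures is None else list(measures)
    unknown = set(names) - set(MEASURE_NAMES)
    if unknown:
        raise ValueError(f"unknown measure(s): {sorted(unknown)}")
    out: dict[str, float] = {}
    if "AD" in names:
        out["AD"] = average_degree(W)
    if "ACC" in names:
        out["ACC"] = average_clustering(W, weighted=clustering_weighted)[1]
    if "T" in names:
        out["T"] = transitivity(W)
    if "As" in names:
        out["As"] = assortativity(W)
    if "Den" in names:
        out["Den"] = density(W)
    if {"CC", "ASP", "E", "D"} & set(names):
        d = distance_matrix(W, mode=distance_mode)
        if "CC" in names:
            out["CC"] = float(np.nanmean(closeness(d)))
        if {"ASP", "E", "D"} & set(names):
            asp, e, diam = path_summaries(d)
            if "ASP" in names:
                out["ASP"] = asp
            if "E" in names:
                out["E"] = e
            if "D" in names:
                out["D"] = diam
    if "CPD" in names:
        out["CPD"] = betweenness_cpd(W, d_mode=distance_mode)[1]
    if {"AW", "skewness", "kurtosis"} & set(names):
        aw, _, _, skew, kurt = weight_moments(W)
        if "AW" in names:
            out["AW"] = aw
        if "skewness" in names:
            out["skewness"] = skew
        if "kurtosis" in names:
            out["kurtosis"] = kurt
    return {name: out[name] for name in names}


class NetworkMeasureExtractor(TransformerMixin, BaseEstimator):
    """Transformer mapping adjacency matrices to a measures table.

    ``transform`` takes a list of weighted adjacency matrices and returns a
    :class:`pandas.DataFrame` with one row per input graph and one column
    per measure.
    """

    def __init__(self, clustering_weighted: bool = True,
                 distance_mode: str = "shortest_path",
                 measures: list[str] | None = None):
        self.clustering_weighted = clustering_weighted
        self.distance_mode = distance_mode
        self.measures = measures

    def fit(self, X, y=None):
        self.n_features_in_ = 1
        return self

    def transform(self, X) -> pd.DataFrame:
        rows = [compute_all(W, self.clustering_weighted, self.distance_mode,
                            self.measures) for W in X]
        names = self.measures if self.measures is not None else MEASURE_NAMES
        return pd.DataFrame(rows, columns=list(names))
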