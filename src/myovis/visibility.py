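"""Normalized-weight vertical visibility networks.

Each sample of a normalized epoch becomes a node.  Two nodes i < j are
linked when they are adjacent (j = i + 1) or when every intermediate sample
lies strictly below the straight line joining them:

    x_n < x_j + (x_j - x_i) * (n - j) / (j - i)    for all i < n < j.

A linked pair receives weight W_ij = |x_i - x_j| + 1; unlinked pairs get 0.
Strictness matters: an intermediate sample of equal height blocks the line
of sight, but the adjacency clause guarantees the chain 1-2-...-N is always
present, so every graph is connected and no equal-amplitude plateau can
isolate a node.

The visibility criterion above is algebraically identical to the classical
natural-visibility form x_n < x_j + (x_i - x_j)(j - n)/(j - i); a test
asserts the pointwise identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import InvariantViolationError
from .preprocessing import Epoch


def visible(x, i: int, j: int) -> bool:
    """Vertical visibility between nodes ``i`` and ``j`` (0-based, i < j).

    Implements the algebraic criterion literally; adjacent nodes are always
    visible.
    """
    x = np.asarray(x, dtype=float)
    if not 0 <= i < j <= x.size - 1:
        raise IndexError(f"need 0 <= i < j < N, got i={i}, j={j}, N={x.size}")
    if j == i + 1:
        return True
    n = np.arange(i + 1, j)
    return bool(np.all(x[n] < x[j] + (x[j] - x[i]) * (n - j) / (j - i)))


def build_weighted_adjacency(epoch) -> np.ndarray:
    """Weighted adjacency matrix of an epoch's visibility network.

    ``epoch`` may be an :class:`~myovis.preprocessing.Epoch` or a bare
    amplitude sequence.  Runs an O(N^2) forward sweep per node: j is visible
    from i exactly when the chord slope (x_j - x_i)/(j - i) strictly exceeds
    the running maximum of the slopes to every intermediate sample, with
    early termination once no remaining sample can beat that maximum.
    """
    x = np.asarray(epoch.x if isinstance(epoch, Epoch) else epoch, dtype=float)
    n = x.size
    if n < 2:
        raise InvariantViolationError("epoch must have at least 2 samples")
    xmax = x.max()
    W = np.zeros((n, n))
    for i in range(n - 1):
        W[i, i + 1] = W[i + 1, i] = abs(x[i] - x[i + 1]) + 1.0
        max_slope = x[i + 1] - x[i]          # slope to the first intermediate
        for j in range(i + 2, n):
            slope = (x[j] - x[i]) / (j - i)
            if slope > max_slope:
                W[i, j] = W[j, i] = abs(x[i] - x[j]) + 1.0
                max_slope = slope
            else:
                max_slope = max(max_slope, slope)
            # no later sample can exceed max_slope once even the global
            # maximum viewed from i falls below it
            if j < n - 1 and (xmax - x[i]) / (j + 1 - i) <= max_slope:
                break
    return W


@dataclass(frozen=True)
class LinkSet:
    """Unordered visible node pairs {i, j}, i < j (0-based), and their count."""

    pairs: frozenset
    n_nodes: int

    @property
    def L(self) -> int:
        return len(self.pairs)


def link_set(W: np.ndarray) -> LinkSet:
    """Extract the link set of a weighted adjacency matrix."""
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise InvariantViolationError("adjacency matrix must be square")
    if not np.array_equal(W, W.T):
        raise InvariantViolationError("adjacency matrix must be symmetric")
    iu, ju = np.nonzero(np.triu(W, k=1))
    return LinkSet(pairs=frozenset(zip(iu.tolist(), ju.tolist())), n_nodes=W.shape[0])


class VisibilityGraphTransformer(TransformerMixin, BaseEstimator):
    """Transformer mapping epochs to weighted adjacency matrices."""

    def fit(self, X, y=None):
        self.n_features_in_ = 1
        return self

    def transform(self, X) -> list[np.ndarray]:
        return [build_weighted_adjacency(ep) for ep in X]
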