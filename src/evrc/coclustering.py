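"""Contact graph and co-clustering coefficients.

A distance matrix induces an undirected graph on the bins: an edge joins
``i`` and ``j`` exactly when ``D_ij`` is finite (equivalently, the input
frequency was positive).  The classical clustering coefficient of a node
measures how densely its neighbors interconnect,

    CC_i = 2 e_i / (k_i (k_i - 1)),

with ``k_i`` the degree and ``e_i`` the number of edges among the
neighbors of ``i``.  The *co*-clustering coefficient generalizes this to a
pair of bins: take the union ``U_ij = N_i | N_j`` of their neighbor sets
(``k_ij`` nodes) and count every graph edge with both endpoints inside
``U_ij`` (``e_ij`` edges):

    coCC_ij = 2 e_ij / (k_ij (k_ij - 1)).

Bins that co-cluster in space — e.g. bins of the same topologically
associating domain — share densely interconnected neighborhoods and get
coCC near 1; these values weight the optimizer's error vectors and are
computed once from the data, never during iteration.  Degenerate unions
(``k_ij <= 1``) are defined as coCC = 0: no clustering evidence.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._types import CoCCMatrix, DistanceMatrix
from .errors import ValidationError

__all__ = [
    "ContactGraph",
    "CoCCMatrix",
    "build_graph",
    "node_clustering",
    "cocc_pair",
    "cocc_matrix",
]


@dataclass
class ContactGraph:
    """Undirected bin-contact graph as a boolean adjacency matrix (no self-loops)."""

    adjacency: np.ndarray

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency, dtype=bool)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValidationError("adjacency must be square")
        if not np.array_equal(A, A.T):
            raise ValidationError("adjacency must be symmetric")
        A = A.copy()
        np.fill_diagonal(A, False)
        self.adjacency = A

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def neighbors(self, i: int) -> np.ndarray:
        """Indices of the neighbor set N_i."""
        self._check_node(i)
        return np.flatnonzero(self.adjacency[i])

    def degree(self, i: int) -> int:
        return int(self.adjacency[i].sum())

    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def _check_node(self, i: int) -> None:
        if not (0 <= i < self.n_nodes):
            raise IndexError(f"node {i} outside 0..{self.n_nodes - 1}")


def build_graph(D: DistanceMatrix) -> ContactGraph:
    """Edge (i, j) exactly where the off-diagonal target distance is finite."""
    return ContactGraph(adjacency=D.finite_mask())


def node_clustering(g: ContactGraph, i: int) -> float:
    """Clustering coefficient CC_i; 0 when the degree is at most 1."""
    nbrs = g.neighbors(i)
    k = len(nbrs)
    if k <= 1:
        return 0.0
    e = int(g.adjacency[np.ix_(nbrs, nbrs)].sum()) // 2
    return 2.0 * e / (k * (k - 1))


def cocc_pair(g: ContactGraph, i: int, j: int) -> float:
    """Co-clustering coefficient of a bin pair (direct set-based evaluation).

    Counts every edge of the whole graph whose two endpoints both lie in
    ``U_ij = N_i | N_j``; when ``i`` and ``j`` are adjacent each belongs to
    the other's neighbor set, so the (i, j) edge itself qualifies.
    """
    g._check_node(i)
    g._check_node(j)
    if i == j:
        raise ValidationError("co-clustering coefficient requires two distinct bins")
    union = g.adjacency[i] | g.adjacency[j]
    k = int(union.sum())
    if k <= 1:
        return 0.0
    idx = np.flatnonzero(union)
    e = int(g.adjacency[np.ix_(idx, idx)].sum()) // 2
    return 2.0 * e / (k * (k - 1))


def cocc_matrix(g: ContactGraph) -> CoCCMatrix:
    """All-pairs co-clustering coefficients.

    Equivalent to calling :func:`cocc_pair` for every pair but organized
    around one matrix identity: with ``C_ij = V \\ U_ij`` the complement of
    the neighbor union,

        e_ij = m - sum_{a in C} deg(a) + e(C, C),

    where ``m`` is the total edge count.  The first two terms vectorize as
    matrix products; the residual ``e(C, C)`` is evaluated per pair on the
    smaller of the union/complement supports using packed bitsets, which
    makes dense contact graphs (complement empty) and sparse ones (union
    small) both cheap.
    """
    A = g.adjacency
    n = g.n_nodes
    vals = np.zeros((n, n))
    if n < 2:
        return CoCCMatrix(values=vals)
    Af = A.astype(np.float64)
    deg = Af.sum(axis=1)
    m = deg.sum() / 2.0
    common = Af @ Af  # |N_i & N_j|
    k_union = deg[:, None] + deg[None, :] - common
    B = ~A  # complement rows; diagonal True (a node unadjacent to itself)
    np.fill_diagonal(B, True)
    term2 = (B * deg) @ B.T.astype(np.float64)  # sum of degrees over C_ij
    Ap = np.packbits(A, axis=1)
    Bp = np.packbits(B, axis=1)
    iu, ju = np.triu_indices(n, 1)
    for i, j in zip(iu, ju):
        k = int(round(k_union[i, j]))
        if k <= 1:
            continue
        cb = Bp[i] & Bp[j]
        if k <= n - k:
            # sparse side: count edges inside the union directly
            ub = Ap[i] | Ap[j]
            idx = np.flatnonzero(np.unpackbits(ub, count=n))
            e = int(np.bitwise_count(Ap[idx] & ub).sum()) / 2.0
        else:
            # dense side: subtract edges touching the complement
            if cb.any():
                idx = np.flatnonzero(np.unpackbits(cb, count=n))
                q = int(np.bitwise_count(Ap[idx] & cb).sum())
            else:
                q = 0
            e = m - term2[i, j] + q / 2.0
        vals[i, j] = vals[j, i] = 2.0 * e / (k * (k - 1))
    return CoCCMatrix(values=vals)
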