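"""Graph clustering for two-stage designs: Markov clustering and reLDG.

MCL operates on the weighted adjacency (edge spillover probabilities when
present), so strongly tied nodes end up in the same cluster and the number of
clusters is discovered rather than supplied.  reLDG is a capacity-constrained
streaming partitioner that takes the desired number of clusters as input and
ignores edge weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .graph import AttributedGraph, Clustering

__all__ = ["MCLParams", "ReLDGParams", "mcl_cluster", "reldg_cluster"]


@dataclass
class MCLParams:
    inflation: float = 2.0
    expansion: int = 2
    self_loop: bool = True
    prune_tol: float = 1e-5
    max_iter: int = 100
    conv_tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")
        if self.expansion < 2:
            raise ValueError("expansion must be >= 2")


@dataclass
class ReLDGParams:
    k: int
    passes: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")


def _column_normalize(M: sp.csc_matrix) -> sp.csc_matrix:
    sums = np.asarray(M.sum(axis=0)).ravel()
    sums[sums == 0] = 1.0
    return M @ sp.diags(1.0 / sums)


def mcl_cluster(graph: AttributedGraph, params: MCLParams | None = None) -> Clustering:
    """Markov clustering on the (self-looped) weighted adjacency matrix.

    Iterates expansion (matrix power of the column-stochastic transition
    matrix) and inflation (elementwise power followed by renormalization),
    pruning entries below ``prune_tol``, until the matrix stops changing.
    Clusters are read off the attractor rows; a node claimed by several
    attractors goes to the lowest-index one.
    """
    params = params or MCLParams()
    n = graph.n
    if n == 0:
        raise ValueError("graph is empty")
    w = graph.edge_p if graph.edge_p is not None else np.ones(graph.m)
    if graph.m and w.min() < 0:
        raise ValueError("edge weights must be non-negative")
    rows = np.concatenate([graph.edges[:, 0], graph.edges[:, 1]])
    cols = np.concatenate([graph.edges[:, 1], graph.edges[:, 0]])
    vals = np.concatenate([w, w])
    A = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsc()
    if params.self_loop:
        # self-loop weight = node's max incident weight (1 for isolated nodes)
        maxw = np.zeros(n)
        if graph.m:
            np.maximum.at(maxw, graph.edges[:, 0], w)
            np.maximum.at(maxw, graph.edges[:, 1], w)
        maxw[maxw == 0] = 1.0
        A = A + sp.diags(maxw)
    M = _column_normalize(A.tocsc())

    converged = False
    for _ in range(params.max_iter):
        last = M.copy()
        # expand
        P = M
        for _ in range(params.expansion - 1):
            P = P @ M
        M = P
        # inflate + renormalize
        M = M.power(params.inflation)
        M = _column_normalize(M.tocsc())
        # prune tiny entries (keeps the matrix sparse)
        M.data[M.data < params.prune_tol] = 0.0
        M.eliminate_zeros()
        M = _column_normalize(M)
        diff = abs(M - last)
        if diff.nnz == 0 or diff.max() < params.conv_tol:
            converged = True
            break
    if not converged:
        warnings.warn("MCL did not converge within max_iter; using current state",
                      RuntimeWarning, stacklevel=2)

    M = M.tocsr()
    attractors = np.flatnonzero(M.diagonal() > params.prune_tol)
    labels = np.full(n, -1, dtype=np.int64)
    for a in attractors:
        row = M.indices[M.indptr[a]:M.indptr[a + 1]]
        for v in np.append(row, a):
            if labels[v] == -1:  # overlap -> lowest-index attractor wins
                labels[v] = a
    # nodes pruned out of every attractor row: follow their strongest column entry
    Mc = M.tocsc()
    for v in np.flatnonzero(labels == -1):
        col = Mc.indices[Mc.indptr[v]:Mc.indptr[v + 1]]
        if col.size:
            vals_v = Mc.data[Mc.indptr[v]:Mc.indptr[v + 1]]
            target = col[np.argmax(vals_v)]
            labels[v] = labels[target] if labels[target] != -1 else v
        else:
            labels[v] = v
    return Clustering.relabel(labels)


def reldg_cluster(graph: AttributedGraph, params: ReLDGParams) -> Clustering:
    """Restreaming linear deterministic greedy partition into k balanced clusters.

    Nodes are streamed in a seeded random order (a fresh order each pass) and
    greedily assigned to the cluster maximizing
    ``|N(v) ∩ cluster| * (1 - size/capacity)`` subject to ``size < capacity``
    with ``capacity = ceil(n/k)``; ties break to the lowest cluster index.
    Later passes re-assign each node against the previous partition.
    """
    n, k = graph.n, params.k
    if k > n:
        raise ValueError("k must be <= n")
    capacity = -(-n // k)
    rng = np.random.default_rng(params.seed)
    indptr, indices, _ = graph.csr()
    # `view` holds each node's latest known label: this pass's if already
    # streamed, else the previous pass's.  Each pass fills clusters afresh.
    view = np.full(n, -1, dtype=np.int64)

    for _ in range(max(1, params.passes)):
        order = rng.permutation(n)
        sizes = np.zeros(k, dtype=np.int64)
        for v in order:
            neigh = indices[indptr[v]:indptr[v + 1]]
            counts = np.zeros(k)
            if neigh.size:
                placed = view[neigh]
                placed = placed[placed >= 0]
                if placed.size:
                    counts = np.bincount(placed, minlength=k).astype(float)
            score = counts * (1.0 - sizes / capacity)
            score[sizes >= capacity] = -np.inf
            best = int(np.argmax(score))  # argmax takes the lowest index on ties
            view[v] = best
            sizes[best] += 1
    # relabel to contiguous ids (some clusters may be empty for tiny graphs)
    return Clustering.relabel(view)
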