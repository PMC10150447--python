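"""Node-pair similarity and edge spillover probability assignment.

Tie strength is used as a proxy for the probability that influence crosses an
edge.  The default metric is one minus the normalized L2 distance between the
two endpoints' attribute vectors; cosine and generalized (Ruzicka) Jaccard
similarity are available as alternatives.  All metrics map into ``[0, 1]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import AttributedGraph

__all__ = ["SimilaritySpec", "pairwise_similarity", "similarity_matrix",
           "assign_edge_probabilities"]

L2BASED = "l2"
COSINE = "cosine"
JACCARD = "jaccard"

THEORETICAL_MAX = "theoretical"
OBSERVED_MAX = "observed"


@dataclass
class SimilaritySpec:
    """How to turn two attribute vectors into a similarity in [0, 1].

    For the L2-based metric the distance is divided by a normalizer ``M``:
    with ``theoretical`` normalization ``M = (high - low) * sqrt(d)`` (the
    diameter of the attribute box, known for synthetic data); with
    ``observed`` normalization ``M`` is the maximum pairwise distance found in
    the data (sampled for large n, then clamped).  ``attr_low``/``attr_high``
    are also used to shift vectors to be non-negative for Jaccard.
    """

    metric: str = L2BASED
    normalization: str = THEORETICAL_MAX
    attr_low: float = -1.0
    attr_high: float = 1.0

    def __post_init__(self) -> None:
        if self.metric not in (L2BASED, COSINE, JACCARD):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.normalization not in (THEORETICAL_MAX, OBSERVED_MAX):
            raise ValueError(f"unknown normalization {self.normalization!r}")

    def l2_normalizer(self, d: int, X: np.ndarray | None = None,
                      rng: np.random.Generator | None = None) -> float:
        if self.normalization == THEORETICAL_MAX:
            return (self.attr_high - self.attr_low) * np.sqrt(d)
        if X is None:
            raise ValueError("observed normalization requires the attribute matrix")
        return observed_max_distance(X, rng=rng)


def observed_max_distance(X: np.ndarray, max_pairs: int = 1_000_000,
                          rng: np.random.Generator | None = None) -> float:
    """Max pairwise Euclidean distance, over a uniform pair sample when large."""
    n = X.shape[0]
    total = n * (n - 1) // 2
    if total <= max_pairs:
        from scipy.spatial.distance import pdist

        d = pdist(X)
        return float(d.max()) if d.size else 1.0
    rng = rng or np.random.default_rng(0)
    i = rng.integers(n, size=max_pairs)
    j = rng.integers(n, size=max_pairs)
    keep = i != j
    d = np.linalg.norm(X[i[keep]] - X[j[keep]], axis=1)
    return float(d.max())


def pairwise_similarity(x_i, x_j, spec: SimilaritySpec,
                        normalizer: float | None = None) -> float:
    """Similarity of two attribute vectors under ``spec``, in [0, 1]."""
    x_i = np.asarray(x_i, dtype=float)
    x_j = np.asarray(x_j, dtype=float)
    if x_i.shape != x_j.shape or x_i.ndim != 1:
        raise ValueError("attribute vectors must share one dimension d")
    return float(similarity_matrix(x_i[None, :], x_j[None, :], spec,
                                   normalizer=normalizer)[0, 0])


def similarity_matrix(A: np.ndarray, B: np.ndarray, spec: SimilaritySpec,
                      normalizer: float | None = None) -> np.ndarray:
    """All-pairs similarity between the rows of ``A`` and the rows of ``B``."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape[1] != B.shape[1]:
        raise ValueError("dimension mismatch")
    d = A.shape[1]
    if spec.metric == L2BASED:
        M = normalizer if normalizer is not None else spec.l2_normalizer(d)
        if M <= 0:
            raise ValueError("L2 normalizer must be positive")
        from scipy.spatial.distance import cdist

        sim = 1.0 - cdist(A, B) / M
        return np.clip(sim, 0.0, 1.0)
    if spec.metric == COSINE:
        na = np.linalg.norm(A, axis=1)
        nb = np.linalg.norm(B, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            sim = (A @ B.T) / np.outer(na, nb)
        sim[~np.isfinite(sim)] = 0.0  # zero vectors have no direction
        return np.clip(sim, 0.0, 1.0)  # negatives clamp to "no affinity"
    # generalized Jaccard on vectors shifted to be non-negative
    U = A - spec.attr_low
    V = B - spec.attr_low
    mins = np.minimum(U[:, None, :], V[None, :, :]).sum(axis=2)
    maxs = np.maximum(U[:, None, :], V[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = mins / maxs
    sim[maxs == 0] = 1.0  # both at the lower bound: identical vectors
    return np.clip(sim, 0.0, 1.0)


def assign_edge_probabilities(graph: AttributedGraph,
                              mode: float | SimilaritySpec) -> AttributedGraph:
    """Set ``e.p`` on every edge.

    ``mode`` is either a fixed probability (the same value on every edge) or a
    :class:`SimilaritySpec`, in which case ``e.p = sim(x_i, x_j)`` for each
    edge ``(i, j)``.
    """
    if isinstance(mode, SimilaritySpec):
        if graph.X is None:
            raise ValueError("similarity-based probabilities require node attributes")
        M = None
        if mode.metric == L2BASED:
            M = mode.l2_normalizer(graph.X.shape[1], X=graph.X)
        if graph.m:
            xi = graph.X[graph.edges[:, 0]]
            xj = graph.X[graph.edges[:, 1]]
            p = _rowwise_similarity(xi, xj, mode, M)
        else:
            p = np.empty(0)
        return graph.with_edge_p(p)
    p_fixed = float(mode)
    if not 0.0 <= p_fixed <= 1.0:
        raise ValueError("fixed probability must lie in [0, 1]")
    return graph.with_edge_p(np.full(graph.m, p_fixed))


def _rowwise_similarity(A: np.ndarray, B: np.ndarray, spec: SimilaritySpec,
                        normalizer: float | None) -> np.ndarray:
    """Similarity of paired rows (A[k], B[k]) — the edge-wise fast path."""
    if spec.metric == L2BASED:
        M = normalizer if normalizer is not None else spec.l2_normalizer(A.shape[1])
        sim = 1.0 - np.linalg.norm(A - B, axis=1) / M
        return np.clip(sim, 0.0, 1.0)
    if spec.metric == COSINE:
        na = np.linalg.norm(A, axis=1)
        nb = np.linalg.norm(B, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            sim = np.einsum("ij,ij->i", A, B) / (na * nb)
        sim[~np.isfinite(sim)] = 0.0
        return np.clip(sim, 0.0, 1.0)
    U = A - spec.attr_low
    V = B - spec.attr_low
    mins = np.minimum(U, V).sum(axis=1)
    maxs = np.maximum(U, V).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = mins / maxs
    sim[maxs == 0] = 1.0
    return np.clip(sim, 0.0, 1.0)
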