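"""Maximum-weight matching helpers shared by the node-matching designs."""

from __future__ import annotations

import networkx as nx
import numpy as np

from .spillover import SimilaritySpec, similarity_matrix

__all__ = ["similarity_node_matching"]

# exact blossom matching is cubic; above this the candidate graph is sparsified
EXACT_LIMIT = 500
TOP_K = 50


def similarity_node_matching(X: np.ndarray, nodes: np.ndarray,
                             spec: SimilaritySpec | None = None,
                             exact_limit: int = EXACT_LIMIT,
                             top_k: int = TOP_K) -> list[tuple[int, int]]:
    """Maximum-weight matching of ``nodes`` on attribute similarity.

    For up to ``exact_limit`` nodes the matching is exact (blossom algorithm on
    the complete similarity graph).  Above that the candidate graph is
    sparsified to each node's ``top_k`` most similar peers before matching.
    Returns matched pairs as (node, node) tuples in graph ids.
    """
    spec = spec or SimilaritySpec()
    nodes = np.asarray(nodes, dtype=np.int64)
    nn = nodes.size
    if nn < 2:
        return []
    g = nx.Graph()
    if nn <= exact_limit:
        sim = similarity_matrix(X[nodes], X[nodes], spec)
        iu, ju = np.triu_indices(nn, k=1)
        g.add_weighted_edges_from(
            (int(nodes[i]), int(nodes[j]), float(sim[i, j]))
            for i, j in zip(iu, ju)
        )
    else:
        from sklearn.neighbors import NearestNeighbors

        # similarity is monotone decreasing in L2 distance for the default
        # metric, so nearest neighbors in attribute space are the best matches
        knn = NearestNeighbors(n_neighbors=min(top_k + 1, nn)).fit(X[nodes])
        dist, idx = knn.kneighbors(X[nodes])
        seen = set()
        for a in range(nn):
            for b_pos in range(1, idx.shape[1]):
                b = int(idx[a, b_pos])
                if b == a:
                    continue
                key = (min(a, b), max(a, b))
                if key in seen:
                    continue
                seen.add(key)
                s = float(similarity_matrix(X[nodes[a]][None], X[nodes[b]][None], spec)[0, 0])
                g.add_edge(int(nodes[a]), int(nodes[b]), weight=s)
        k_nodes = set(g.nodes)
        for v in nodes:
            if int(v) not in k_nodes:
                g.add_node(int(v))
    mate = nx.max_weight_matching(g, maxcardinality=True)
    return [(int(a), int(b)) for a, b in mate]
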