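"""Cluster matching for total treatment effect estimation.

After a graph has been clustered (stage 1, interference minimization), this
module pairs up clusters with similar covariate distributions (stage 2,
selection bias minimization) and assigns each matched pair to opposite arms.
Cluster similarity is built from *node matches* across clusters:

* node rules — TNM0..TNM3 (threshold at the 0/25/50/75th percentile of the
  pairwise node-similarity distribution) or BNM (each node matched to its
  single most similar node in another cluster);
* cluster weights — E (negated Euclidean distance of attribute means),
  C (matched-pair count), S (mean matched similarity), and MC / MS / MSS,
  which first restrict matches by a maximum-weight bipartite matching so each
  node counts at most once;
* candidate rules — TCM0..TCM3 (keep cluster pairs above a weight percentile)
  or GCM (each cluster proposes only its best partner).

The final cluster pairing maximizes total weight subject to each cluster
matching at most once; unmatched clusters sit out the experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .graph import CONTROL, EXCLUDED, TREATED, AttributedGraph, Clustering, Design
from .spillover import L2BASED, SimilaritySpec, similarity_matrix

__all__ = [
    "NodeMatchSet",
    "ClusterGraph",
    "CMatchOptions",
    "UnsupportedCombination",
    "node_matches",
    "cluster_weight",
    "all_cluster_weights",
    "build_cluster_graph",
    "match_clusters",
    "cmatch_design",
    "enumerate_option_combinations",
]

NODE_RULES = ("tnm0", "tnm1", "tnm2", "tnm3", "bnm")
WEIGHT_METHODS = ("e", "c", "s", "mc", "ms", "mss")
CLUSTER_RULES = ("tcm0", "tcm1", "tcm2", "tcm3", "gcm")

MAX_QUANTILE_PAIRS = 1_000_000


class UnsupportedCombination(ValueError):
    """Raised for option bundles that are undefined (BNM with MC/MS/MSS)."""


@dataclass
class NodeMatchSet:
    """Cross-cluster node matches under a TNM or BNM rule.

    Match indicators are materialized lazily per cluster pair via
    :meth:`pair_block`, so the full n-by-n indicator never needs to exist.
    """

    rule: str
    clustering: Clustering
    X: np.ndarray
    spec: SimilaritySpec
    alpha: float | None = None          # TNM threshold (None: match all pairs)
    best: np.ndarray | None = None      # BNM: best cross-cluster partner
    best_sim: np.ndarray | None = None
    normalizer: float | None = None     # fixed L2 normalizer for consistency

    def _sim(self, nodes_i: np.ndarray, nodes_j: np.ndarray) -> np.ndarray:
        return similarity_matrix(self.X[nodes_i], self.X[nodes_j], self.spec,
                                 normalizer=self.normalizer)

    def pair_block(self, ci: int, cj: int):
        """(members_i, members_j, similarity block, match mask) for one cluster pair."""
        if ci == cj:
            raise ValueError("node matches are only defined across clusters")
        vi = self.clustering.members(ci)
        vj = self.clustering.members(cj)
        sim = self._sim(vi, vj)
        if self.rule.startswith("tnm"):
            mask = np.ones_like(sim, dtype=bool) if self.alpha is None else sim > self.alpha
        else:
            mask = (self.best[vi][:, None] == vj[None, :]) | \
                   (self.best[vj][None, :] == vi[:, None])
        return vi, vj, sim, mask


def _similarity_sample(X: np.ndarray, spec: SimilaritySpec, normalizer: float | None,
                       seed: int) -> np.ndarray:
    """Similarities of all node pairs, or of a uniform 10^6-pair sample when large."""
    n = X.shape[0]
    total = n * (n - 1) // 2
    if total <= MAX_QUANTILE_PAIRS:
        iu, ju = np.triu_indices(n, k=1)
        return _paired(X[iu], X[ju], spec, normalizer)
    rng = np.random.default_rng(seed)
    i = rng.integers(n, size=MAX_QUANTILE_PAIRS)
    j = rng.integers(n, size=MAX_QUANTILE_PAIRS)
    keep = i != j
    return _paired(X[i[keep]], X[j[keep]], spec, normalizer)


def _paired(A: np.ndarray, B: np.ndarray, spec: SimilaritySpec,
            normalizer: float | None) -> np.ndarray:
    from .spillover import _rowwise_similarity

    return _rowwise_similarity(A, B, spec, normalizer)


def node_matches(clustering: Clustering, X: np.ndarray,
                 spec: SimilaritySpec | None = None, rule: str = "tnm2",
                 seed: int = 0) -> NodeMatchSet:
    """Build the cross-cluster node match set for a TNM or BNM rule.

    For TNM*q* the threshold is the *q*-th quartile of the pairwise node
    similarity distribution (quartile 0 matches every cross-cluster pair);
    for BNM each node is matched to its most similar node overall, required to
    lie in a different cluster.
    """
    spec = spec or SimilaritySpec()
    rule = rule.lower()
    if rule not in NODE_RULES:
        raise ValueError(f"unknown node rule {rule!r}")
    if clustering.n != X.shape[0]:
        raise ValueError("clustering and attributes must cover the same nodes")
    normalizer = None
    if spec.metric == L2BASED:
        normalizer = spec.l2_normalizer(X.shape[1], X=X)
    ms = NodeMatchSet(rule=rule, clustering=clustering, X=X, spec=spec,
                      normalizer=normalizer)
    if rule.startswith("tnm"):
        q = int(rule[3])
        if q == 0:
            ms.alpha = None  # liberal: all cross-cluster pairs match
        else:
            sims = _similarity_sample(X, spec, normalizer, seed)
            if sims.size and np.ptp(sims) == 0:
                import warnings

                warnings.warn("degenerate similarity distribution; quantiles collapse",
                              RuntimeWarning, stacklevel=2)
            ms.alpha = float(np.quantile(sims, q * 0.25)) if sims.size else 0.0
    else:
        ms.best, ms.best_sim = _best_cross_cluster(clustering, X, spec, normalizer)
    return ms


def _best_cross_cluster(clustering: Clustering, X: np.ndarray, spec: SimilaritySpec,
                        normalizer: float | None, chunk: int = 512):
    n = X.shape[0]
    labels = clustering.labels
    best = np.full(n, -1, dtype=np.int64)
    best_sim = np.full(n, -np.inf)
    for s in range(0, n, chunk):
        e = min(s + chunk, n)
        sim = similarity_matrix(X[s:e], X, spec, normalizer=normalizer)
        same = labels[s:e][:, None] == labels[None, :]
        sim[same] = -np.inf  # forbids self-matches too (same cluster)
        best[s:e] = np.argmax(sim, axis=1)
        best_sim[s:e] = sim[np.arange(e - s), best[s:e]]
    lonely = ~np.isfinite(best_sim)  # single-cluster corner: no cross match
    best[lonely] = -1
    return best, best_sim


def cluster_weight(ci: int, cj: int, method: str, matchset: NodeMatchSet) -> float:
    """Similarity weight ``w_ij`` of one cluster pair under a weight method."""
    method = method.lower()
    if method not in WEIGHT_METHODS:
        raise ValueError(f"unknown weight method {method!r}")
    if method == "e":
        vi = matchset.clustering.members(ci)
        vj = matchset.clustering.members(cj)
        # negated distance of attribute means: larger = more similar, max 0
        return -float(np.linalg.norm(matchset.X[vi].mean(axis=0)
                                     - matchset.X[vj].mean(axis=0)))
    if method in ("mc", "ms", "mss") and matchset.rule == "bnm":
        raise UnsupportedCombination("BNM matches each node at most once already; "
                                     "MC/MS/MSS are defined for TNM only")
    vi, vj, sim, mask = matchset.pair_block(ci, cj)
    if method == "c":
        return float(mask.sum())
    if method == "s":
        cnt = mask.sum()
        return float(sim[mask].sum() / cnt) if cnt else 0.0
    # MC / MS / MSS: maximum-weight bipartite matching on the admissible pairs
    ii, jj = np.nonzero(mask)
    if ii.size == 0:
        return 0.0
    g = nx.Graph()
    g.add_weighted_edges_from(
        (("a", int(i)), ("b", int(j)), float(sim[i, j])) for i, j in zip(ii, jj)
    )
    mate = nx.max_weight_matching(g, maxcardinality=True)
    sims = np.array([sim[a[1], b[1]] if a[0] == "a" else sim[b[1], a[1]]
                     for a, b in mate])
    if method == "mc":
        return float(len(mate))
    if method == "ms":
        return float(sims.mean()) if sims.size else 0.0
    return float(sims.sum())


def all_cluster_weights(matchset_or_none: NodeMatchSet | None, method: str,
                        clustering: Clustering | None = None,
                        X: np.ndarray | None = None) -> dict[tuple[int, int], float]:
    """``w_ij`` for every unordered cluster pair."""
    method = method.lower()
    if method == "e":
        if matchset_or_none is not None:
            clustering = matchset_or_none.clustering
            X = matchset_or_none.X
        if clustering is None or X is None:
            raise ValueError("E weights need a clustering and attributes")
        g = clustering.g
        means = np.vstack([X[clustering.members(c)].mean(axis=0) for c in range(g)])
        weights = {}
        for i in range(g):
            diffs = np.linalg.norm(means[i + 1:] - means[i], axis=1)
            for off, dist in enumerate(diffs):
                weights[(i, i + 1 + off)] = -float(dist)
        return weights
    if matchset_or_none is None:
        raise ValueError(f"weight method {method!r} needs a node match set")
    g = matchset_or_none.clustering.g
    return {(i, j): cluster_weight(i, j, method, matchset_or_none)
            for i in range(g) for j in range(i + 1, g)}


@dataclass
class ClusterGraph:
    """Cluster-level candidate-match graph for the pairing objective."""

    g: int
    weights: dict[tuple[int, int], float]
    candidate_edges: list[tuple[int, int]]
    matching: list[tuple[int, int]] = field(default_factory=list)


def build_cluster_graph(weights: dict[tuple[int, int], float],
                        rule: str = "tcm2", g: int | None = None) -> ClusterGraph:
    """Keep the cluster pairs eligible for matching.

    TCM*q* keeps pairs whose weight exceeds the *q*-th quartile of the cluster
    weight distribution (quartile 0 keeps all pairs); GCM keeps, for each
    cluster, only the edge to its top-weight partner.
    """
    rule = rule.lower()
    if rule not in CLUSTER_RULES:
        raise ValueError(f"unknown cluster rule {rule!r}")
    if g is None:
        g = 1 + max((max(p) for p in weights), default=-1)
    if rule == "gcm":
        cands: set[tuple[int, int]] = set()
        for c in range(g):
            best, best_w = None, -np.inf
            for (i, j), w in weights.items():
                if c in (i, j) and w > best_w:
                    best, best_w = (i, j), w
            if best is not None:
                cands.add(best)
        edges = sorted(cands)
    else:
        q = int(rule[3])
        if q == 0 or not weights:
            edges = sorted(weights)
        else:
            beta = float(np.quantile(np.fromiter(weights.values(), dtype=float),
                                     q * 0.25))
            edges = sorted(p for p, w in weights.items() if w > beta)
    return ClusterGraph(g=g, weights=dict(weights), candidate_edges=edges)


def match_clusters(cg: ClusterGraph, maxcardinality: bool = False) -> list[tuple[int, int]]:
    """Maximum-weight matching over the candidate cluster pairs.

    Maximizes the total weight of disjoint matched pairs (each cluster used at
    most once).  ``maxcardinality`` first maximizes the number of matched
    pairs, which is the right mode for weights on a negated-distance scale.
    """
    g = nx.Graph()
    g.add_nodes_from(range(cg.g))
    g.add_weighted_edges_from((i, j, cg.weights[(i, j)]) for i, j in cg.candidate_edges)
    mate = nx.max_weight_matching(g, maxcardinality=maxcardinality)
    cg.matching = sorted((min(a, b), max(a, b)) for a, b in mate)
    return cg.matching


@dataclass
class CMatchOptions:
    """Option bundle naming the node rule, weight method and cluster rule.

    The default TNM2 + C + TCM2 pairs clusters by the count of node matches
    above the median node similarity, keeping cluster pairs above the median
    cluster weight.
    """

    node_rule: str = "tnm2"
    weight: str = "c"
    cluster_rule: str = "tcm2"
    spec: SimilaritySpec = field(default_factory=SimilaritySpec)

    def __post_init__(self) -> None:
        self.node_rule = self.node_rule.lower() if self.node_rule else self.node_rule
        self.weight = self.weight.lower()
        self.cluster_rule = self.cluster_rule.lower()
        if self.weight not in WEIGHT_METHODS:
            raise ValueError(f"unknown weight method {self.weight!r}")
        if self.cluster_rule not in CLUSTER_RULES:
            raise ValueError(f"unknown cluster rule {self.cluster_rule!r}")
        if self.weight != "e" and self.node_rule not in NODE_RULES:
            raise ValueError(f"unknown node rule {self.node_rule!r}")
        if self.weight in ("mc", "ms", "mss") and self.node_rule == "bnm":
            raise UnsupportedCombination("BNM cannot be combined with MC/MS/MSS")


def cmatch_design(graph: AttributedGraph, clustering: Clustering,
                  options: CMatchOptions | None = None, seed: int = 0,
                  X: np.ndarray | None = None) -> Design:
    """Full cluster-matching design: node matches → weights → pairing → arms.

    Every matched cluster pair is split by a seeded coin, one cluster to
    treatment and one to control (member nodes inherit the arm); clusters left
    unmatched are excluded from the experiment.
    """
    options = options or CMatchOptions()
    X = X if X is not None else graph.X
    if X is None:
        raise ValueError("cluster matching requires node attributes")
    if clustering.n != graph.n:
        raise ValueError("clustering must cover the graph")
    if options.weight == "e":
        weights = all_cluster_weights(None, "e", clustering=clustering, X=X)
    else:
        ms = node_matches(clustering, X, spec=options.spec, rule=options.node_rule,
                          seed=seed)
        weights = all_cluster_weights(ms, options.weight)
    cg = build_cluster_graph(weights, rule=options.cluster_rule, g=clustering.g)
    # E weights are <= 0, so pure weight maximization would match nothing;
    # maximizing cardinality first keeps as many nodes in the experiment as
    # possible, then breaks ties by similarity.
    pairs = match_clusters(cg, maxcardinality=(options.weight == "e"))
    if not pairs:
        raise ValueError("no experiment constructed: cluster matching is empty")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(13,)))
    arm = np.full(graph.n, EXCLUDED, dtype=np.int8)
    for ci, cj in pairs:
        if rng.random() < 0.5:
            ci, cj = cj, ci
        arm[clustering.members(ci)] = TREATED
        arm[clustering.members(cj)] = CONTROL
    return Design(arm)


def enumerate_option_combinations() -> list[CMatchOptions | tuple[str, str, str]]:
    """All 115 defined option bundles (plus raising combinations marked by tuple).

    Returns CMatchOptions for the 115 supported combinations; the 15 undefined
    BNM x {MC, MS, MSS} x cluster-rule bundles are not included (constructing
    them raises :class:`UnsupportedCombination`).
    """
    combos: list[CMatchOptions] = []
    for cr in CLUSTER_RULES:
        combos.append(CMatchOptions(node_rule=None, weight="e", cluster_rule=cr))
    for w in ("c", "s", "mc", "ms", "mss"):
        for nr in NODE_RULES:
            if nr == "bnm" and w in ("mc", "ms", "mss"):
                continue
            for cr in CLUSTER_RULES:
                combos.append(CMatchOptions(node_rule=nr, weight=w, cluster_rule=cr))
    return combos
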