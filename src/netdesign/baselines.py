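"""Comparison designs: node randomization, node matching, and stratified
cluster randomization (CR / CBR)."""

from __future__ import annotations

import numpy as np

from .clustering import ReLDGParams, reldg_cluster
from .graph import CONTROL, TREATED, AttributedGraph, Clustering, Design
from .matching import similarity_node_matching
from .spillover import SimilaritySpec

__all__ = ["randomized_design", "match_design", "cbr_design"]


def randomized_design(graph: AttributedGraph, seed: int = 0) -> Design:
    """Uniform node-level split into two arms, ignoring the network."""
    n = graph.n
    if n < 2:
        raise ValueError("need at least two nodes")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    cut = n // 2 + ((n % 2) if rng.random() < 0.5 else 0)
    arm = np.full(n, CONTROL, dtype=np.int8)
    arm[perm[:cut]] = TREATED
    return Design(arm)


def match_design(graph: AttributedGraph, seed: int = 0,
                 spec: SimilaritySpec | None = None,
                 X: np.ndarray | None = None) -> Design:
    """Pair the most similar nodes and split every pair across arms.

    Uses maximum-weight matching on attribute similarity over all nodes (exact
    for moderate n, top-k sparsified above), then a seeded coin per pair; an
    unmatched node (odd n) is randomized.
    """
    X = X if X is not None else graph.X
    if X is None:
        raise ValueError("match design requires node attributes")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(3,)))
    pairs = similarity_node_matching(X, np.arange(graph.n), spec=spec)
    arm = np.full(graph.n, CONTROL, dtype=np.int8)
    matched = set()
    for a, b in pairs:
        if rng.random() < 0.5:
            a, b = b, a
        arm[a] = TREATED
        arm[b] = CONTROL
        matched.update((a, b))
    for v in range(graph.n):
        if v not in matched:
            arm[v] = TREATED if rng.random() < 0.5 else CONTROL
    return Design(arm)


def _greedy_strata(means: np.ndarray) -> list[tuple[int, ...]]:
    """Pair clusters into strata of two by greedy nearest attribute means."""
    g = means.shape[0]
    unpaired = list(range(g))
    strata: list[tuple[int, ...]] = []
    while len(unpaired) > 1:
        c = unpaired.pop(0)
        dists = np.linalg.norm(means[unpaired] - means[c], axis=1)
        j = int(np.argmin(dists))
        partner = unpaired.pop(j)
        strata.append((c, partner))
    if unpaired:
        strata.append((unpaired[0],))
    return strata


def cbr_design(graph: AttributedGraph, k: int, seed: int = 0, mode: str = "cbr",
               clustering: Clustering | None = None,
               X: np.ndarray | None = None) -> Design:
    """Stratified cluster designs on a reLDG partition.

    Clusters are paired into strata of two by greedy nearest-neighbor on their
    attribute mean vectors.  ``mode="cbr"`` sends one whole cluster per
    stratum to each arm (a coin decides which); ``mode="cr"`` randomizes at
    the node level within each stratum.  Neither mode excludes nodes, except
    that an odd cluster count leaves one stratum of a single cluster, which is
    then randomized whole (CBR) or node-wise (CR).
    """
    mode = mode.lower()
    if mode not in ("cr", "cbr"):
        raise ValueError("mode must be 'cr' or 'cbr'")
    X = X if X is not None else graph.X
    if X is None:
        raise ValueError("stratification requires node attributes")
    if clustering is None:
        clustering = reldg_cluster(graph, ReLDGParams(k=k, seed=seed))
    g = clustering.g
    if mode == "cbr" and g < 2:
        raise ValueError("CBR needs at least two clusters")
    means = np.vstack([X[clustering.members(c)].mean(axis=0) for c in range(g)])
    strata = _greedy_strata(means)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(5,)))
    arm = np.full(graph.n, CONTROL, dtype=np.int8)
    for stratum in strata:
        if mode == "cbr":
            if len(stratum) == 2:
                ci, cj = stratum
                if rng.random() < 0.5:
                    ci, cj = cj, ci
                arm[clustering.members(ci)] = TREATED
                arm[clustering.members(cj)] = CONTROL
            else:
                lab = TREATED if rng.random() < 0.5 else CONTROL
                arm[clustering.members(stratum[0])] = lab
        else:
            nodes = np.concatenate([clustering.members(c) for c in stratum])
            perm = rng.permutation(nodes)
            cut = nodes.size // 2 + ((nodes.size % 2) if rng.random() < 0.5 else 0)
            arm[perm[:cut]] = TREATED
            arm[perm[cut:]] = CONTROL
    return Design(arm)
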