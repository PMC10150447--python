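"""Independent-set randomization for direct treatment effect estimation.

The design selects a maximal independent set (MIS) of the graph and randomizes
treatment and control *within* it; the remaining nodes become bystanders,
excluded from the experiment.  Because no two experimental nodes are adjacent,
there are no peer effects between (or within) the arms, and whatever influence
bystanders exert is balanced across arms in expectation by the randomization,
so the difference-in-means estimate isolates the direct effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import CONTROL, EXCLUDED, TREATED, AttributedGraph, Design
from .matching import similarity_node_matching
from .spillover import SimilaritySpec

__all__ = ["MISResult", "greedy_mis", "causeis_design", "bystander_balance"]


@dataclass
class MISResult:
    """A maximal independent set and its complement (the bystanders)."""

    members: np.ndarray
    bystanders: np.ndarray
    restarts_used: int

    @property
    def size(self) -> int:
        return int(self.members.size)


def greedy_mis(graph: AttributedGraph, seed: int = 0, restarts: int = 1) -> MISResult:
    """Greedy maximal independent set from a seeded random node permutation.

    Scans a random permutation once, adding each node iff none of its
    neighbors was already added — O(|E|).  With ``restarts > 1`` the largest
    set over independently seeded scans is returned, approximating a maximum
    independent set at extra cost.
    """
    if graph.n == 0:
        raise ValueError("graph is empty")
    indptr, indices, _ = graph.csr()
    rng = np.random.default_rng(seed)
    best: np.ndarray | None = None
    for _ in range(max(1, restarts)):
        order = rng.permutation(graph.n)
        in_set = np.zeros(graph.n, dtype=bool)
        blocked = np.zeros(graph.n, dtype=bool)
        for v in order:
            if blocked[v]:
                continue
            in_set[v] = True
            blocked[indices[indptr[v]:indptr[v + 1]]] = True
            blocked[v] = True
        members = np.flatnonzero(in_set)
        if best is None or members.size > best.size:
            best = members
    bystanders = np.setdiff1d(np.arange(graph.n), best, assume_unique=True)
    return MISResult(members=best, bystanders=bystanders, restarts_used=max(1, restarts))


def causeis_design(graph: AttributedGraph, seed: int = 0, use_matching: bool = False,
                   restarts: int = 1, spec: SimilaritySpec | None = None) -> Design:
    """Randomize treatment/control over a greedy MIS; everyone else is a bystander.

    With ``use_matching`` (the matched variant), MIS nodes are paired by
    maximum-weight matching on attribute similarity and each pair is split one
    to each arm, reducing selection bias on small graphs; an unmatched node is
    assigned by coin flip.
    """
    mis = greedy_mis(graph, seed=seed, restarts=restarts)
    if mis.size < 2:
        raise ValueError("independent set too small to form two arms")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(7,)))
    arm = np.full(graph.n, EXCLUDED, dtype=np.int8)
    if use_matching:
        if graph.X is None:
            raise ValueError("matched variant requires node attributes")
        pairs = similarity_node_matching(graph.X, mis.members, spec=spec)
        matched = set()
        for a, b in pairs:
            if rng.random() < 0.5:
                a, b = b, a
            arm[a] = TREATED
            arm[b] = CONTROL
            matched.update((a, b))
        for v in mis.members:
            if int(v) not in matched:
                arm[v] = TREATED if rng.random() < 0.5 else CONTROL
    else:
        perm = rng.permutation(mis.members)
        half = mis.size // 2
        extra_to_treated = bool(rng.random() < 0.5)
        cut = half + (mis.size % 2 if extra_to_treated else 0)
        arm[perm[:cut]] = TREATED
        arm[perm[cut:]] = CONTROL
    return Design(arm)


def bystander_balance(graph: AttributedGraph, design: Design) -> float:
    """Signed percentage gap between bystander→treated and bystander→control edges.

    ``100/|E| * (#edges TREATED–EXCLUDED - #edges CONTROL–EXCLUDED)``; close to
    zero means bystander influence is balanced across the two arms.
    """
    if graph.m == 0:
        raise ValueError("graph has no edges")
    a_u = design.arm[graph.edges[:, 0]]
    a_v = design.arm[graph.edges[:, 1]]
    te = np.sum(((a_u == TREATED) & (a_v == EXCLUDED))
                | ((a_u == EXCLUDED) & (a_v == TREATED)))
    ce = np.sum(((a_u == CONTROL) & (a_v == EXCLUDED))
                | ((a_u == EXCLUDED) & (a_v == CONTROL)))
    return 100.0 * (int(te) - int(ce)) / graph.m
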