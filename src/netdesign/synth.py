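"""Synthetic attributed graphs: preferential attachment and forest fire.

These generators reproduce the study conditions used throughout the package's
simulation experiments: Barabási–Albert graphs with attachment count ``m = 3``,
undirected forest-fire graphs with forward/backward burning probabilities
``p_f = p_b = 0.3``, and ``d = 10`` i.i.d. Uniform(-1, 1) attributes per node.
Generation is a pure, seeded function of the configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .graph import AttributedGraph

__all__ = ["SynthConfig", "barabasi_albert", "forest_fire", "uniform_attributes",
           "generate"]


@dataclass
class SynthConfig:
    """Parameters for synthetic graph + attribute generation.

    ``model`` is ``"ba"`` (preferential attachment) or ``"ff"`` (forest fire).
    For BA the seed graph is the complete graph on ``m`` nodes, so the edge
    count is exactly ``C(m, 2) + m*(n - m)``.  Attributes are ``d`` i.i.d.
    Uniform(attr_low, attr_high) values per node, independent of structure.
    """

    n: int
    model: str = "ba"
    m: int = 3
    p_f: float = 0.3
    p_b: float = 0.3
    d: int = 10
    attr_low: float = -1.0
    attr_high: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.model not in ("ba", "ff"):
            raise ValueError("model must be 'ba' or 'ff'")
        if self.model == "ba" and not 1 <= self.m < self.n:
            raise ValueError("BA requires 1 <= m < n")
        if not (0 <= self.p_f <= 1 and 0 <= self.p_b <= 1):
            raise ValueError("burning probabilities must lie in [0, 1]")
        if self.d < 1:
            raise ValueError("d must be >= 1")


def barabasi_albert(cfg: SynthConfig) -> AttributedGraph:
    """Preferential-attachment graph seeded with the complete graph on m nodes.

    Each arriving node attaches to ``m`` distinct existing nodes chosen with
    probability proportional to their current degree.
    """
    if cfg.n <= cfg.m:
        raise ValueError("BA requires n > m")
    rng = np.random.default_rng(cfg.seed)
    g = nx.barabasi_albert_graph(cfg.n, cfg.m, seed=rng,
                                 initial_graph=nx.complete_graph(cfg.m))
    edges = np.array(sorted(tuple(sorted(e)) for e in g.edges()), dtype=np.int64)
    return AttributedGraph(cfg.n, edges)


def forest_fire(cfg: SynthConfig) -> AttributedGraph:
    """Undirected forest-fire growth.

    Each new node picks a uniform ambassador among existing nodes, links to
    it, and recursively "burns" through the graph: at every burned node the
    fire spreads to a geometric number of not-yet-visited neighbors with mean
    ``p_f/(1-p_f) + p_b/(1-p_b)`` (forward and backward draws, merged because
    the graph is undirected).  The new node links to every burned node, so the
    result is connected.
    """
    rng = np.random.default_rng(cfg.seed)
    adj: list[list[int]] = [[] for _ in range(cfg.n)]
    edges: list[tuple[int, int]] = []
    for v in range(1, cfg.n):
        ambassador = int(rng.integers(v))
        visited = {v, ambassador}
        burned = [ambassador]
        queue = [ambassador]
        while queue:
            w = queue.pop()
            cands = [x for x in adj[w] if x not in visited]
            if not cands:
                continue
            # number of successes before first failure: mean p/(1-p)
            k = _geometric_burn(rng, cfg.p_f) + _geometric_burn(rng, cfg.p_b)
            k = min(k, len(cands))
            if k == 0:
                continue
            picks = rng.choice(len(cands), size=k, replace=False)
            for idx in picks:
                x = cands[idx]
                visited.add(x)
                burned.append(x)
                queue.append(x)
        for w in burned:
            edges.append((min(v, w), max(v, w)))
            adj[v].append(w)
            adj[w].append(v)
    if edges:
        arr = np.array(edges, dtype=np.int64)
        arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
    else:
        arr = np.empty((0, 2), dtype=np.int64)
    return AttributedGraph(cfg.n, arr)


def _geometric_burn(rng: np.random.Generator, p: float) -> int:
    if p >= 1.0:
        # degenerate: burn everything reachable
        return np.iinfo(np.int64).max
    if p <= 0.0:
        return 0
    # numpy geometric counts trials to first success with prob (1-p);
    # subtracting 1 gives the number of successes before the first failure.
    return int(rng.geometric(1.0 - p)) - 1


def uniform_attributes(cfg: SynthConfig, graph: AttributedGraph) -> AttributedGraph:
    """Attach d i.i.d. Uniform(attr_low, attr_high) attributes per node."""
    rng = np.random.default_rng(_attr_seed(cfg.seed))
    X = rng.uniform(cfg.attr_low, cfg.attr_high, size=(graph.n, cfg.d))
    return graph.with_attributes(X)


def _attr_seed(seed: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=seed, spawn_key=(101,))


def generate(cfg: SynthConfig) -> AttributedGraph:
    """Generate structure + attributes in one call (pure function of cfg)."""
    graph = barabasi_albert(cfg) if cfg.model == "ba" else forest_fire(cfg)
    return uniform_attributes(cfg, graph)
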