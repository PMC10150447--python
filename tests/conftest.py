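import numpy as np
import pytest

from netdesign import AttributedGraph


def make_planted_graph(k: int = 4, size: int | list = 30, p_in: float = 0.3,
                       n_out: int | None = None, d: int = 4, seed: int = 0,
                       center_scale: float = 0.6) -> AttributedGraph:
    """Planted-cluster graph: k dense blocks with distinct attribute centers
    and a handful of sparse inter-block edges."""
    rng = np.random.default_rng(seed)
    sizes = [size] * k if np.isscalar(size) else list(size)
    k = len(sizes)
    starts = np.concatenate([[0], np.cumsum(sizes)])
    n = int(starts[-1])
    block = np.repeat(np.arange(k), sizes)
    edges = set()
    for c in range(k):
        base, sz = int(starts[c]), sizes[c]
        for i in range(sz):
            for j in range(i + 1, sz):
                if rng.random() < p_in:
                    edges.add((base + i, base + j))
    n_out = n_out if n_out is not None else k
    added = 0
    while added < n_out:
        u, v = int(rng.integers(n)), int(rng.integers(n))
        if block[u] != block[v]:
            key = (min(u, v), max(u, v))
            if key not in edges:
                edges.add(key)
                added += 1
    centers = rng.uniform(-center_scale, center_scale, size=(k, d))
    X = np.vstack([
        np.clip(centers[c] + rng.uniform(-0.3, 0.3, size=(sizes[c], d)), -1, 1)
        for c in range(k)
    ])
    return AttributedGraph.from_edges(n, sorted(edges), X=X)


@pytest.fixture
def triangle() -> AttributedGraph:
    return AttributedGraph.from_edges(3, [(0, 1), (1, 2), (0, 2)])


@pytest.fixture
def path3() -> AttributedGraph:
    return AttributedGraph.from_edges(3, [(0, 1), (1, 2)])


@pytest.fixture
def cycle4() -> AttributedGraph:
    return AttributedGraph.from_edges(4, [(0, 1), (1, 2), (2, 3), (0, 3)])


@pytest.fixture
def star4() -> AttributedGraph:
    """K_{1,3}: center 0 with three leaves."""
    return AttributedGraph.from_edges(4, [(0, 1), (0, 2), (0, 3)])


@pytest.fixture
def planted() -> AttributedGraph:
    return make_planted_graph(seed=7)
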