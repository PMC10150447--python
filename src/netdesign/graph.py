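"""Core data model: attributed graphs, designs, clusterings, outcomes, and text I/O.

The package works on undirected simple graphs with contiguous integer node ids
``0..n-1``.  Node attributes are held in a dense ``(n, d)`` matrix, and edges may
carry a spillover probability ``e.p`` in ``[0, 1]`` — the per-edge probability
that influence crosses the edge during an experiment.

File formats are plain text: an edge list (``u v [p]`` per line, ``#`` comments,
tab/comma/space delimited), an attribute table with header ``node_id,f1,...,fd``,
a design table ``node_id,arm``, and a clustering table ``node_id,cluster``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TREATED",
    "CONTROL",
    "EXCLUDED",
    "ARM_NAMES",
    "AttributedGraph",
    "Design",
    "Clustering",
    "Outcome",
    "GraphParseError",
    "load_graph",
    "save_graph",
    "load_attributes",
    "save_attributes",
    "load_design",
    "save_design",
    "load_clustering",
    "save_clustering",
    "filter_min_degree",
]

# Arm codes follow the V_0 (control), V_1 (treatment), V_2 (bystander) convention.
CONTROL = 0
TREATED = 1
EXCLUDED = 2
ARM_NAMES = {CONTROL: "CONTROL", TREATED: "TREATED", EXCLUDED: "EXCLUDED"}
ARM_CODES = {v: k for k, v in ARM_NAMES.items()}


class GraphParseError(ValueError):
    """Malformed graph/attribute/design input file."""


def _canonical_edges(edges: np.ndarray) -> np.ndarray:
    """Sort endpoints within rows (u < v) and rows lexicographically."""
    edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
    lo = edges.min(axis=1)
    hi = edges.max(axis=1)
    out = np.column_stack([lo, hi])
    order = np.lexsort((out[:, 1], out[:, 0]))
    return out[order]


@dataclass
class AttributedGraph:
    """Undirected simple graph with optional node attributes and edge probabilities.

    Parameters
    ----------
    n : int
        Number of nodes; ids are ``0..n-1``.
    edges : (m, 2) int array
        Unordered pairs stored with ``u < v``, no duplicates, no self-loops.
    edge_p : (m,) float array, optional
        Per-edge spillover probability in ``[0, 1]``, aligned with ``edges``.
    X : (n, d) float array, optional
        Node attribute matrix.
    original_ids : (n,) array, optional
        Original node labels (as read from file) for round-tripping output.
    """

    n: int
    edges: np.ndarray
    edge_p: np.ndarray | None = None
    X: np.ndarray | None = None
    original_ids: np.ndarray | None = None
    _csr: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        self.validate()

    def validate(self) -> None:
        m = self.edges.shape[0]
        if m:
            if self.edges.min() < 0 or self.edges.max() >= self.n:
                raise ValueError("edge endpoint out of range")
            if np.any(self.edges[:, 0] == self.edges[:, 1]):
                raise ValueError("self-loops are not allowed")
            if np.any(self.edges[:, 0] > self.edges[:, 1]):
                raise ValueError("edges must be stored with u < v")
            dedup = np.unique(self.edges, axis=0)
            if dedup.shape[0] != m:
                raise ValueError("duplicate edges are not allowed")
        if self.edge_p is not None:
            self.edge_p = np.asarray(self.edge_p, dtype=float)
            if self.edge_p.shape != (m,):
                raise ValueError("edge_p must align with edges")
            if m and (self.edge_p.min() < 0 or self.edge_p.max() > 1):
                raise ValueError("edge probabilities must lie in [0, 1]")
        if self.X is not None:
            self.X = np.asarray(self.X, dtype=float)
            if self.X.ndim != 2 or self.X.shape[0] != self.n:
                raise ValueError("attributes must cover every node with equal dimension")

    # -- derived structure -------------------------------------------------
    @property
    def m(self) -> int:
        return int(self.edges.shape[0])

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n, dtype=np.int64)
        if self.m:
            np.add.at(deg, self.edges[:, 0], 1)
            np.add.at(deg, self.edges[:, 1], 1)
        return deg

    def csr(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Adjacency in CSR form: (indptr, indices, edge_index).

        ``edge_index[j]`` maps the directed slot back to the row of ``edges``
        (and hence ``edge_p``) it came from.
        """
        if self._csr is None:
            src = np.concatenate([self.edges[:, 0], self.edges[:, 1]])
            dst = np.concatenate([self.edges[:, 1], self.edges[:, 0]])
            eid = np.tile(np.arange(self.m, dtype=np.int64), 2)
            order = np.argsort(src, kind="stable")
            src, dst, eid = src[order], dst[order], eid[order]
            indptr = np.zeros(self.n + 1, dtype=np.int64)
            np.add.at(indptr, src + 1, 1)
            np.cumsum(indptr, out=indptr)
            self._csr = (indptr, dst, eid)
        return self._csr

    def neighbors(self, i: int) -> np.ndarray:
        indptr, indices, _ = self.csr()
        return indices[indptr[i] : indptr[i + 1]]

    def with_edge_p(self, edge_p: np.ndarray) -> "AttributedGraph":
        return AttributedGraph(self.n, self.edges, edge_p=edge_p, X=self.X,
                               original_ids=self.original_ids)

    def with_attributes(self, X: np.ndarray) -> "AttributedGraph":
        return AttributedGraph(self.n, self.edges, edge_p=self.edge_p, X=X,
                               original_ids=self.original_ids)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        if self.edge_p is not None:
            g.add_weighted_edges_from(
                (int(u), int(v), float(p))
                for (u, v), p in zip(self.edges, self.edge_p)
            )
        else:
            g.add_edges_from((int(u), int(v)) for u, v in self.edges)
        return g

    @classmethod
    def from_edges(cls, n: int, edges, edge_p=None, X=None) -> "AttributedGraph":
        arr = np.asarray(list(edges), dtype=np.int64).reshape(-1, 2)
        if arr.size:
            lo, hi = arr.min(axis=1), arr.max(axis=1)
            arr = np.column_stack([lo, hi])
            order = np.lexsort((arr[:, 1], arr[:, 0]))
            arr = arr[order]
            if edge_p is not None:
                edge_p = np.asarray(edge_p, dtype=float)[order]
        return cls(n, arr, edge_p=edge_p, X=X)


@dataclass
class Design:
    """Per-node arm assignment: TREATED, CONTROL or EXCLUDED (bystander)."""

    arm: np.ndarray

    def __post_init__(self) -> None:
        self.arm = np.asarray(self.arm, dtype=np.int8)
        if self.arm.ndim != 1:
            raise ValueError("arm must be a 1-d array over nodes")
        if not np.isin(self.arm, [CONTROL, TREATED, EXCLUDED]).all():
            raise ValueError("invalid arm label")

    @property
    def n(self) -> int:
        return self.arm.shape[0]

    @property
    def treated(self) -> np.ndarray:
        return np.flatnonzero(self.arm == TREATED)

    @property
    def control(self) -> np.ndarray:
        return np.flatnonzero(self.arm == CONTROL)

    @property
    def excluded(self) -> np.ndarray:
        return np.flatnonzero(self.arm == EXCLUDED)


@dataclass
class Clustering:
    """Total, non-overlapping node partition with contiguous labels 0..g-1."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1:
            raise ValueError("labels must be 1-d")
        if self.labels.size:
            uniq = np.unique(self.labels)
            if uniq[0] != 0 or uniq[-1] != uniq.size - 1:
                raise ValueError("cluster labels must be contiguous 0..g-1")

    @property
    def n(self) -> int:
        return self.labels.shape[0]

    @property
    def g(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    def members(self, c: int) -> np.ndarray:
        return np.flatnonzero(self.labels == c)

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.g)

    @staticmethod
    def relabel(raw: np.ndarray) -> "Clustering":
        """Map arbitrary labels to contiguous ids in order of first appearance."""
        raw = np.asarray(raw)
        _, first = np.unique(raw, return_index=True)
        order = raw[np.sort(first)]
        lut = {lab: i for i, lab in enumerate(order)}
        return Clustering(np.array([lut[x] for x in raw], dtype=np.int64))


@dataclass
class Outcome:
    """Realized binary outcomes, one per node."""

    y: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.int8)
        if self.y.ndim != 1 or not np.isin(self.y, [0, 1]).all():
            raise ValueError("outcomes must be binary and 1-d")


# ---------------------------------------------------------------------------
# text I/O
# ---------------------------------------------------------------------------

_SPLIT = re.compile(r"[,\s]+")


def _tokens(line: str) -> list[str]:
    return [t for t in _SPLIT.split(line.strip()) if t]


def load_graph(edge_path, weighted: bool = False) -> AttributedGraph:
    """Read an undirected edge list (``u v [p]`` per line).

    Reversed duplicates collapse to one edge (first weight wins); node ids are
    remapped to ``0..n-1`` with the original labels kept on the graph.
    """
    pairs: list[tuple[str, str]] = []
    probs: list[float] = []
    with open(edge_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            toks = _tokens(line)
            want = 3 if weighted else 2
            if len(toks) != want:
                raise GraphParseError(
                    f"{edge_path}: line {lineno}: expected {want} fields, got {len(toks)}"
                )
            u, v = toks[0], toks[1]
            if u == v:
                raise GraphParseError(f"{edge_path}: line {lineno}: self-loop on node {u!r}")
            if weighted:
                try:
                    p = float(toks[2])
                except ValueError as exc:
                    raise GraphParseError(
                        f"{edge_path}: line {lineno}: non-numeric weight {toks[2]!r}"
                    ) from exc
                if not 0.0 <= p <= 1.0:
                    raise GraphParseError(
                        f"{edge_path}: line {lineno}: weight {p} outside [0, 1]"
                    )
                probs.append(p)
            pairs.append((u, v))

    labels = sorted({x for pair in pairs for x in pair}, key=_label_key)
    index = {lab: i for i, lab in enumerate(labels)}
    if all(_label_key(lab)[0] == 0 for lab in labels):
        labels = [int(lab) for lab in labels]  # keep integer labels as integers
    n = len(labels)
    seen: dict[tuple[int, int], float | None] = {}
    for k, (u, v) in enumerate(pairs):
        iu, iv = index[u], index[v]
        key = (min(iu, iv), max(iu, iv))
        if key not in seen:
            seen[key] = probs[k] if weighted else None
    if seen:
        edges = _canonical_edges(np.array(list(seen.keys()), dtype=np.int64))
        order_keys = [tuple(e) for e in edges]
        edge_p = np.array([seen[k] for k in order_keys], dtype=float) if weighted else None
    else:
        edges = np.empty((0, 2), dtype=np.int64)
        edge_p = np.empty(0) if weighted else None
    return AttributedGraph(n, edges, edge_p=edge_p,
                           original_ids=np.array(labels, dtype=object))


def _label_key(label: str):
    try:
        return (0, int(label), "")
    except ValueError:
        return (1, 0, label)


def _orig(graph: AttributedGraph, i: int):
    return graph.original_ids[i] if graph.original_ids is not None else i


def save_graph(graph: AttributedGraph, edge_path) -> None:
    with open(edge_path, "w") as fh:
        for k, (u, v) in enumerate(graph.edges):
            if graph.edge_p is not None:
                fh.write(f"{_orig(graph, u)} {_orig(graph, v)} {float(graph.edge_p[k])!r}\n")
            else:
                fh.write(f"{_orig(graph, u)} {_orig(graph, v)}\n")


def load_attributes(attr_path, graph: AttributedGraph) -> AttributedGraph:
    """Attach a delimited attribute table (header ``node_id,f1,...,fd``)."""
    with open(attr_path) as fh:
        lines = [l.strip() for l in fh if l.strip() and not l.startswith("#")]
    if not lines:
        raise GraphParseError(f"{attr_path}: empty attribute table")
    header = _tokens(lines[0])
    d = len(header) - 1
    if d < 1:
        raise GraphParseError(f"{attr_path}: need at least one attribute column")
    if graph.original_ids is not None:
        index = {str(lab): i for i, lab in enumerate(graph.original_ids)}
    else:
        index = {str(i): i for i in range(graph.n)}
    X = np.full((graph.n, d), np.nan)
    seen = np.zeros(graph.n, dtype=bool)
    for lineno, line in enumerate(lines[1:], start=2):
        toks = _tokens(line)
        if len(toks) != d + 1:
            raise GraphParseError(
                f"{attr_path}: line {lineno}: expected {d + 1} fields, got {len(toks)}"
            )
        if toks[0] not in index:
            raise GraphParseError(f"{attr_path}: line {lineno}: unknown node id {toks[0]!r}")
        i = index[toks[0]]
        if seen[i]:
            raise GraphParseError(f"{attr_path}: line {lineno}: duplicate row for node {toks[0]!r}")
        seen[i] = True
        try:
            X[i] = [float(t) for t in toks[1:]]
        except ValueError as exc:
            raise GraphParseError(f"{attr_path}: line {lineno}: non-numeric cell") from exc
    if not seen.all():
        missing = _orig(graph, int(np.flatnonzero(~seen)[0]))
        raise GraphParseError(f"{attr_path}: missing attribute row for node {missing!r}")
    return graph.with_attributes(X)


def save_attributes(graph: AttributedGraph, attr_path) -> None:
    if graph.X is None:
        raise ValueError("graph has no attributes")
    d = graph.X.shape[1]
    with open(attr_path, "w") as fh:
        fh.write("node_id," + ",".join(f"f{j + 1}" for j in range(d)) + "\n")
        for i in range(graph.n):
            fh.write(str(_orig(graph, i)) + ","
                     + ",".join(repr(float(x)) for x in graph.X[i]) + "\n")


def save_design(design: Design, path, graph: AttributedGraph | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("node_id,arm\n")
        for i, a in enumerate(design.arm):
            lab = _orig(graph, i) if graph is not None else i
            fh.write(f"{lab},{ARM_NAMES[int(a)]}\n")


def load_design(path, graph: AttributedGraph) -> Design:
    arm = np.full(graph.n, -1, dtype=np.int8)
    if graph.original_ids is not None:
        index = {str(lab): i for i, lab in enumerate(graph.original_ids)}
    else:
        index = {str(i): i for i in range(graph.n)}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("node_id"):
                continue
            toks = _tokens(line)
            if len(toks) != 2 or toks[1].upper() not in ARM_CODES:
                raise GraphParseError(f"{path}: line {lineno}: malformed design row")
            if toks[0] not in index:
                raise GraphParseError(f"{path}: line {lineno}: unknown node id {toks[0]!r}")
            arm[index[toks[0]]] = ARM_CODES[toks[1].upper()]
    if (arm < 0).any():
        raise GraphParseError(f"{path}: design does not cover every node")
    return Design(arm)


def save_clustering(clustering: Clustering, path, graph: AttributedGraph | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("node_id,cluster\n")
        for i, c in enumerate(clustering.labels):
            lab = _orig(graph, i) if graph is not None else i
            fh.write(f"{lab},{int(c)}\n")


def load_clustering(path, graph: AttributedGraph) -> Clustering:
    raw = np.full(graph.n, -1, dtype=np.int64)
    if graph.original_ids is not None:
        index = {str(lab): i for i, lab in enumerate(graph.original_ids)}
    else:
        index = {str(i): i for i in range(graph.n)}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("node_id"):
                continue
            toks = _tokens(line)
            if len(toks) != 2:
                raise GraphParseError(f"{path}: line {lineno}: malformed clustering row")
            if toks[0] not in index:
                raise GraphParseError(f"{path}: line {lineno}: unknown node id {toks[0]!r}")
            raw[index[toks[0]]] = int(toks[1])
    if (raw < 0).any():
        raise GraphParseError(f"{path}: clustering does not cover every node")
    return Clustering.relabel(raw)


def filter_min_degree(graph: AttributedGraph, dmin: int) -> AttributedGraph:
    """Remove nodes with degree below ``dmin`` in a single pass.

    The pass is not iterated to a k-core: with ``dmin=2`` it removes exactly
    the singletons and degree-1 nodes of the *input* graph, the standard
    preprocessing for sparse social graphs.  Remaining ids are re-indexed.
    """
    if dmin < 0:
        raise ValueError("dmin must be >= 0")
    if dmin == 0:
        return graph
    keep = graph.degrees() >= dmin
    new_id = np.cumsum(keep) - 1
    mask = keep[graph.edges[:, 0]] & keep[graph.edges[:, 1]]
    edges = new_id[graph.edges[mask]]
    n_new = int(keep.sum())
    return AttributedGraph(
        n_new,
        edges.reshape(-1, 2),
        edge_p=graph.edge_p[mask] if graph.edge_p is not None else None,
        X=graph.X[keep] if graph.X is not None else None,
        original_ids=graph.original_ids[keep] if graph.original_ids is not None else None,
    )
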