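"""Synthetic outcome model with direct and contagion interference.

Every node carries a latent base activation probability set by its arm: 0.4
for treated nodes and 0.2 for control nodes (bystanders behave like controls
by default), so the true total treatment effect is 0.2 by construction.
Interference then spreads activation across arms:

* ``direct`` — a single pass in which each treated neighbor of an inactive
  control node activates it independently with the edge's spillover
  probability (k treated neighbors give ``1 - prod(1 - e.p)``);
* ``contagion`` — discrete independent-cascade rounds: when an inactive node
  first has at least one *activated* neighbor in a different arm it draws one
  activation trial against those cross-arm edges, newly activated nodes extend
  the frontier, and the process stops when no new activations occur.

Activation is monotone: a node never deactivates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph import CONTROL, EXCLUDED, TREATED, AttributedGraph, Design, Outcome
from .metrics import covariate_distance, cut_statistics, rmse

__all__ = ["SimulationSpec", "simulate_outcomes", "effect_estimate",
           "run_experiment", "ExperimentResult", "derive_seed"]

NONE = "none"
DIRECT = "direct"
CONTAGION = "contagion"


@dataclass
class SimulationSpec:
    """Outcome-model parameters.

    ``ep`` selects the edge spillover probabilities: a float for a fixed value
    on every edge, or ``"edge-weight"`` to use the probabilities already
    assigned on the graph.

    The outcome model defines base activation only for the two arms, so by
    default bystander (excluded) nodes sit outside the simulation entirely:
    they start inactive and edges touching them carry no contagion.  Setting
    ``bystander_spillover=True`` switches to the variant in which bystanders
    carry the control-arm base activation probability and transmit contagion
    as a treatment class of their own.
    """

    p_treat: float = 0.4
    p_control: float = 0.2
    mode: str = NONE
    ep: float | str | None = None
    bystander_spillover: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.p_treat <= 1 and 0 <= self.p_control <= 1):
            raise ValueError("base activation probabilities must lie in [0, 1]")
        if self.mode not in (NONE, DIRECT, CONTAGION):
            raise ValueError("mode must be 'none', 'direct' or 'contagion'")

    @property
    def true_effect(self) -> float:
        return self.p_treat - self.p_control


def _edge_probs(graph: AttributedGraph, spec: SimulationSpec) -> np.ndarray:
    if isinstance(spec.ep, (int, float)):
        return np.full(graph.m, float(spec.ep))
    if graph.edge_p is None:
        raise ValueError("no edge spillover probabilities assigned on the graph")
    return graph.edge_p


def simulate_outcomes(graph: AttributedGraph, design: Design, spec: SimulationSpec,
                      seed: int = 0) -> Outcome:
    """Draw base activations per arm, then spread interference per ``spec``."""
    if design.n != graph.n:
        raise ValueError("design must cover the graph")
    rng = np.random.default_rng(seed)
    base_p = np.empty(graph.n)
    base_p[design.arm == TREATED] = spec.p_treat
    base_p[design.arm == CONTROL] = spec.p_control
    base_p[design.arm == EXCLUDED] = (spec.p_control
                                      if spec.bystander_spillover else 0.0)
    active = rng.random(graph.n) < base_p

    if spec.mode == NONE or graph.m == 0:
        return Outcome(active.astype(np.int8))
    ep = _edge_probs(graph, spec)

    if spec.mode == DIRECT:
        u, v = graph.edges[:, 0], graph.edges[:, 1]
        au, av = design.arm[u], design.arm[v]
        log_keep = np.zeros(graph.n)
        with np.errstate(divide="ignore"):
            l1p = np.log1p(-ep)
        tc = (au == TREATED) & (av == CONTROL)
        np.add.at(log_keep, v[tc], l1p[tc])
        ct = (au == CONTROL) & (av == TREATED)
        np.add.at(log_keep, u[ct], l1p[ct])
        p_act = 1.0 - np.exp(log_keep)
        hit = (~active) & (design.arm == CONTROL) & (rng.random(graph.n) < p_act)
        active |= hit
        return Outcome(active.astype(np.int8))

    # contagion: one activation trial per node, at its first frontier exposure
    u, v = graph.edges[:, 0], graph.edges[:, 1]
    cross = design.arm[u] != design.arm[v]
    if not spec.bystander_spillover:
        cross &= (design.arm[u] != EXCLUDED) & (design.arm[v] != EXCLUDED)
    with np.errstate(divide="ignore"):
        l1p = np.log1p(-ep)
    tried = np.zeros(graph.n, dtype=bool)
    while True:
        log_keep = np.zeros(graph.n)
        exposed = np.zeros(graph.n, dtype=bool)
        live = cross & (active[u] ^ active[v])  # exactly one active endpoint
        src_u = live & active[u]
        np.add.at(log_keep, v[src_u], l1p[src_u])
        exposed[v[src_u]] = True
        src_v = live & active[v]
        np.add.at(log_keep, u[src_v], l1p[src_v])
        exposed[u[src_v]] = True
        eligible = exposed & ~active & ~tried
        if not eligible.any():
            break
        p_act = 1.0 - np.exp(log_keep)
        success = eligible & (rng.random(graph.n) < p_act)
        tried |= eligible
        if not success.any():
            break
        active |= success
    return Outcome(active.astype(np.int8))


def effect_estimate(design: Design, outcome: Outcome) -> float:
    """Difference-in-means estimate; bystanders never enter the estimate."""
    t = design.treated
    c = design.control
    if t.size == 0 or c.size == 0:
        raise ValueError("both arms must be non-empty")
    y = outcome.y
    return float(y[t].mean() - y[c].mean())


def derive_seed(base_seed: int, *keys) -> int:
    """Stable per-stage seed below 2^31 derived from a base seed and stage keys."""
    import hashlib

    h = hashlib.sha256(repr((int(base_seed),) + tuple(keys)).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


@dataclass
class ExperimentResult:
    """Per-run estimates and diagnostics of a replicated experiment."""

    estimates: np.ndarray
    truth: float
    rmse: float
    covariate_distance: np.ndarray
    cut_edge_fraction: np.ndarray
    cut_weight_fraction: np.ndarray
    theta_hat: np.ndarray
    bystander_balance: np.ndarray
    seeds: list[int] = field(default_factory=list)

    @property
    def bias(self) -> float:
        return float(self.estimates.mean() - self.truth)


def run_experiment(make_graph, make_design, spec: SimulationSpec, S: int = 10,
                   base_seed: int = 0) -> ExperimentResult:
    """Replicate (graph → design → outcomes → estimate) S times.

    ``make_graph(seed)`` returns an :class:`AttributedGraph` with edge
    probabilities assigned when the interference mode needs them (use a
    constant function for a fixed graph); ``make_design(graph, seed)`` returns
    a :class:`Design`.  All randomness derives deterministically from
    ``base_seed`` and the run index.
    """
    from .causeis import bystander_balance as _bb

    if S < 1:
        raise ValueError("S must be >= 1")
    est = np.empty(S)
    covd = np.empty(S)
    cutf = np.empty(S)
    cutw = np.empty(S)
    theta = np.empty(S)
    bal = np.empty(S)
    seeds = []
    for s in range(S):
        gs = derive_seed(base_seed, s, "graph")
        ds = derive_seed(base_seed, s, "design")
        os_ = derive_seed(base_seed, s, "outcome")
        seeds.append(os_)
        graph = make_graph(gs)
        design = make_design(graph, ds)
        outcome = simulate_outcomes(graph, design, spec, seed=os_)
        est[s] = effect_estimate(design, outcome)
        covd[s] = (covariate_distance(design, graph.X)
                   if graph.X is not None else np.nan)
        if graph.m:
            stats_graph = graph
            if graph.edge_p is None and isinstance(spec.ep, (int, float)):
                stats_graph = graph.with_edge_p(np.full(graph.m, float(spec.ep)))
            stats = cut_statistics(stats_graph, design)
            cutf[s] = stats["edge_fraction"]
            cutw[s] = stats["weight_fraction"]
            theta[s] = stats["theta_hat"]
            bal[s] = _bb(graph, design)
        else:
            cutf[s] = cutw[s] = theta[s] = bal[s] = np.nan
    return ExperimentResult(
        estimates=est,
        truth=spec.true_effect,
        rmse=rmse(est, spec.true_effect),
        covariate_distance=covd,
        cut_edge_fraction=cutf,
        cut_weight_fraction=cutw,
        theta_hat=theta,
        bystander_balance=bal,
        seeds=seeds,
    )
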