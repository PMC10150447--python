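"""Evaluation metrics: estimation error, covariate balance, cut statistics,
degree-distribution comparison, and the linear-outcome-model bias diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import CONTROL, TREATED, AttributedGraph, Clustering, Design

__all__ = ["rmse", "covariate_distance", "cut_statistics", "degree_comparison",
           "LinearOutcomeModel", "linear_bias"]


def rmse(estimates, truth: float) -> float:
    """Root mean squared error of replicate estimates against the truth."""
    est = np.asarray(estimates, dtype=float)
    if est.size == 0:
        raise ValueError("need at least one estimate")
    return float(np.sqrt(np.mean((est - truth) ** 2)))


def covariate_distance(design: Design, X: np.ndarray) -> float:
    """Euclidean distance between the arm-wise attribute mean vectors.

    Bystander (excluded) nodes are not in the experiment and are omitted.
    """
    if X is None:
        raise ValueError("attributes required")
    t = design.treated
    c = design.control
    if t.size == 0 or c.size == 0:
        raise ValueError("both arms must be non-empty")
    return float(np.linalg.norm(X[t].mean(axis=0) - X[c].mean(axis=0)))


def cut_statistics(graph: AttributedGraph, design: Design) -> dict[str, float]:
    """Cross-arm cut measures: edge fraction, weight fraction, and raw θ̂.

    θ̂ is the sum of edge spillover probabilities over treated–control edges —
    the quantity the weighted-clustering stage minimizes.  Unweighted graphs
    count each edge as weight 1.
    """
    if graph.m == 0:
        raise ValueError("graph has no edges")
    w = graph.edge_p if graph.edge_p is not None else np.ones(graph.m)
    au = design.arm[graph.edges[:, 0]]
    av = design.arm[graph.edges[:, 1]]
    cross = ((au == TREATED) & (av == CONTROL)) | ((au == CONTROL) & (av == TREATED))
    theta = float(w[cross].sum())
    total_w = float(w.sum())
    return {
        "edge_fraction": float(cross.sum()) / graph.m,
        "weight_fraction": theta / total_w if total_w > 0 else 0.0,
        "theta_hat": theta,
    }


def degree_comparison(graph: AttributedGraph, design: Design) -> dict:
    """Per-arm degree histograms (w.r.t. the full graph) and the KS statistic.

    The two-sample Kolmogorov–Smirnov statistic quantifies how different the
    treated and control degree distributions are; excluded nodes are omitted.
    """
    from scipy.stats import ks_2samp

    deg = graph.degrees()
    t = design.treated
    c = design.control
    if t.size == 0 or c.size == 0:
        raise ValueError("both arms must be non-empty")
    dt, dc = deg[t], deg[c]
    top = int(deg.max()) if deg.size else 0
    hist_t = np.bincount(dt, minlength=top + 1)
    hist_c = np.bincount(dc, minlength=top + 1)
    ks = ks_2samp(dt, dc)
    return {
        "treated_hist": hist_t,
        "control_hist": hist_c,
        "ks_statistic": float(ks.statistic),
        "ks_pvalue": float(ks.pvalue),
    }


@dataclass
class LinearOutcomeModel:
    """Linear outcome model y_i = a_i + sum_j B_ij T_j.

    ``B[i, j]`` is the effect of treating node j on node i's expected outcome;
    the diagonal carries the direct effects and off-diagonal entries the
    interference structure.
    """

    a: np.ndarray
    B: np.ndarray

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        if self.B.ndim != 2 or self.B.shape[0] != self.B.shape[1]:
            raise ValueError("B must be square")
        if self.a.shape != (self.B.shape[0],):
            raise ValueError("a must have one intercept per node")
        if not np.isfinite(self.B).all():
            raise ValueError("B must be finite")


def linear_bias(model: LinearOutcomeModel, clustering: Clustering) -> dict[str, float]:
    """Bias diagnostics of cluster randomization under the linear outcome model.

    * ``mu`` — true total effect, ``(1/n) Σ_ij B_ij``;
    * ``mu_cbr`` — effect captured when only within-cluster exposure moves
      with the assignment, ``(1/n) Σ B_ij 1[C(i)=C(j)]``;
    * ``mu_rand`` — effect captured by node randomization, ``(1/n) Σ_i B_ii``;
    * ``relative_bias`` — ``mu / mu_cbr - 1`` (0 when the clustering captures
      all interference mass; NaN-signaled by a raised error when mu_cbr = 0).
    """
    n = model.B.shape[0]
    if clustering.n != n:
        raise ValueError("clustering must cover the model's nodes")
    mu = float(model.B.sum()) / n
    same = clustering.labels[:, None] == clustering.labels[None, :]
    mu_cbr = float(model.B[same].sum()) / n
    mu_rand = float(np.trace(model.B)) / n
    if mu_cbr == 0.0:
        raise ZeroDivisionError("mu_cbr is zero; relative bias undefined")
    return {
        "mu": mu,
        "mu_cbr": mu_cbr,
        "mu_rand": mu_rand,
        "relative_bias": mu / mu_cbr - 1.0,
    }
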