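"""Config-driven replication harness.

Ties together generation → edge weighting → clustering → design → outcome
simulation → metrics, with all randomness derived deterministically from a
base seed, and emits tidy per-run and aggregate tables.

A config is a plain dict (usually read from YAML)::

    dataset:
      synthetic: {model: ff, n: 2000}        # or files: {edges: ..., attributes: ...}
    designs:
      - {method: randomized}
      - {method: causeis}
      - {method: cmatch, cluster_algo: reldg, k: 20,
         node_rule: tnm2, weight: c, cluster_rule: tcm2}
    simulation: {mode: contagion, p_treat: 0.4, p_control: 0.2}
    ep: [0.1, 0.5, edge-weight]
    S: 10
    base_seed: 0
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from . import baselines, causeis, cmatch, synth
from .clustering import MCLParams, ReLDGParams, mcl_cluster, reldg_cluster
from .graph import AttributedGraph, load_attributes, load_graph
from .simulate import SimulationSpec, derive_seed, run_experiment
from .spillover import SimilaritySpec, assign_edge_probabilities

__all__ = ["ExperimentConfig", "SuiteResult", "run_suite", "design_factory",
           "config_hash", "load_preset", "available_presets"]


@dataclass
class ExperimentConfig:
    dataset: dict
    designs: list
    simulation: dict
    ep: list
    S: int = 10
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.S < 1:
            raise ValueError("S must be >= 1")

    @classmethod
    def from_dict(cls, cfg: dict) -> "ExperimentConfig":
        return cls(
            dataset=cfg["dataset"],
            designs=list(cfg["designs"]),
            simulation=dict(cfg.get("simulation", {})),
            ep=list(cfg.get("ep", [None])),
            S=int(cfg.get("S", 10)),
            base_seed=int(cfg.get("base_seed", 0)),
        )

    def to_dict(self) -> dict:
        return {
            "dataset": self.dataset,
            "designs": self.designs,
            "simulation": self.simulation,
            "ep": self.ep,
            "S": self.S,
            "base_seed": self.base_seed,
        }


def config_hash(cfg: ExperimentConfig | dict) -> str:
    d = cfg.to_dict() if isinstance(cfg, ExperimentConfig) else cfg
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# stage factories
# ---------------------------------------------------------------------------

def _graph_factory(dataset: dict, ep_setting):
    """Returns make_graph(seed) regenerating (synthetic) or reusing (files) a graph."""
    needs_weights = ep_setting == "edge-weight"

    if "synthetic" in dataset:
        sd = dict(dataset["synthetic"])

        def make_graph(seed: int) -> AttributedGraph:
            cfg = synth.SynthConfig(
                n=int(sd.get("n", 1000)),
                model=sd.get("model", "ba"),
                m=int(sd.get("m", 3)),
                p_f=float(sd.get("p_f", 0.3)),
                p_b=float(sd.get("p_b", 0.3)),
                d=int(sd.get("d", 10)),
                seed=seed,
            )
            g = synth.generate(cfg)
            if needs_weights:
                g = assign_edge_probabilities(g, SimilaritySpec())
            return g

        return make_graph

    if "files" in dataset:
        fd = dataset["files"]
        g = load_graph(fd["edges"], weighted=bool(fd.get("weighted", False)))
        if "attributes" in fd and fd["attributes"]:
            g = load_attributes(fd["attributes"], g)
        if needs_weights and g.edge_p is None:
            spec = SimilaritySpec(normalization="observed") \
                if fd.get("observed_norm") else SimilaritySpec()
            g = assign_edge_probabilities(g, spec)
        return lambda seed: g

    raise ValueError("dataset must name 'synthetic' or 'files'")


def design_factory(dspec: dict):
    """Map a design spec dict to make_design(graph, seed)."""
    method = dspec["method"].lower()

    if method == "randomized":
        return lambda g, seed: baselines.randomized_design(g, seed=seed)
    if method == "match":
        return lambda g, seed: baselines.match_design(g, seed=seed)
    if method in ("causeis", "causeis_match"):
        restarts = int(dspec.get("restarts", 1))
        return lambda g, seed: causeis.causeis_design(
            g, seed=seed, use_matching=(method == "causeis_match"), restarts=restarts)
    if method in ("cr", "cbr"):
        k = int(dspec.get("k", 2))
        return lambda g, seed: baselines.cbr_design(g, k=k, seed=seed, mode=method)
    if method == "cmatch":
        algo = dspec.get("cluster_algo", "reldg").lower()
        k = int(dspec.get("k", 2))
        options = cmatch.CMatchOptions(
            node_rule=dspec.get("node_rule", "tnm2"),
            weight=dspec.get("weight", "c"),
            cluster_rule=dspec.get("cluster_rule", "tcm2"),
        )

        def make_design(g, seed):
            if algo == "mcl":
                clu = mcl_cluster(g, MCLParams())
            else:
                clu = reldg_cluster(g, ReLDGParams(k=k, seed=derive_seed(seed, "clu")))
            return cmatch.cmatch_design(g, clu, options=options, seed=seed)

        return make_design
    raise ValueError(f"unknown design method {method!r}")


def _design_name(dspec: dict) -> str:
    method = dspec["method"].lower()
    if method == "cmatch":
        return "cmatch_{}_{}+{}+{}".format(
            dspec.get("cluster_algo", "reldg"),
            dspec.get("node_rule", "tnm2"),
            dspec.get("weight", "c"),
            dspec.get("cluster_rule", "tcm2"),
        )
    return method


# ---------------------------------------------------------------------------
# suite runner
# ---------------------------------------------------------------------------

@dataclass
class SuiteResult:
    per_run: pd.DataFrame
    aggregate: pd.DataFrame
    config_hash: str

    def summary(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "cells": self.aggregate.to_dict(orient="records"),
        }


def run_suite(config: ExperimentConfig | dict, log=None) -> SuiteResult:
    """Run every (design × ep setting) cell for S seeded replicates."""
    if isinstance(config, dict):
        config = ExperimentConfig.from_dict(config)
    chash = config_hash(config)
    rows = []
    agg = []
    for ep_setting in config.ep:
        make_graph = _graph_factory(config.dataset, ep_setting)
        for dspec in config.designs:
            name = _design_name(dspec)
            t0 = time.perf_counter()
            spec = SimulationSpec(
                p_treat=float(config.simulation.get("p_treat", 0.4)),
                p_control=float(config.simulation.get("p_control", 0.2)),
                mode=config.simulation.get("mode", "none"),
                ep=ep_setting,
            )
            cell_seed = derive_seed(config.base_seed, name, str(ep_setting))
            res = run_experiment(make_graph, design_factory(dspec), spec,
                                 S=config.S, base_seed=cell_seed)
            for s in range(config.S):
                rows.append({
                    "design": name,
                    "ep": str(ep_setting),
                    "run": s,
                    "estimate": res.estimates[s],
                    "error": res.estimates[s] - res.truth,
                    "covariate_distance": res.covariate_distance[s],
                    "cut_edge_fraction": res.cut_edge_fraction[s],
                    "cut_weight_fraction": res.cut_weight_fraction[s],
                    "theta_hat": res.theta_hat[s],
                    "bystander_balance": res.bystander_balance[s],
                })
            agg.append({
                "design": name,
                "ep": str(ep_setting),
                "S": config.S,
                "truth": res.truth,
                "mean_estimate": float(res.estimates.mean()),
                "rmse": res.rmse,
                "mean_covariate_distance": float(np.nanmean(res.covariate_distance)),
                "mean_cut_edge_fraction": float(np.nanmean(res.cut_edge_fraction)),
                "mean_theta_hat": float(np.nanmean(res.theta_hat)),
                "mean_bystander_balance": float(np.nanmean(res.bystander_balance)),
            })
            if log is not None:
                dt = time.perf_counter() - t0
                print(f"[{chash}] {name} ep={ep_setting}: "
                      f"rmse={agg[-1]['rmse']:.4f} ({dt:.1f}s)",
                      file=log if log is not True else sys.stderr)
    return SuiteResult(per_run=pd.DataFrame(rows), aggregate=pd.DataFrame(agg),
                       config_hash=chash)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def available_presets() -> list[str]:
    pkg = resources.files("netdesign") / "presets"
    return sorted(p.name[:-5] for p in pkg.iterdir() if p.name.endswith(".yaml"))


def load_preset(name: str) -> ExperimentConfig:
    import yaml

    pkg = resources.files("netdesign") / "presets" / f"{name}.yaml"
    with pkg.open() as fh:
        return ExperimentConfig.from_dict(yaml.safe_load(fh))
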