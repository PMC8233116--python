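"""End-to-end experiment orchestration: generate a ground-truth network,
simulate dynamics, infer networks with each algorithm, and score them at
the micro- and macroscale.

Each stochastic stage draws its seed deterministically from the master
seed, the repetition index and the stage name, so stages can be re-run
independently and whole experiments are reproducible bit-for-bit.

``reproduce`` instantiates the four validation studies (Watts-Strogatz
sweep, preferential attachment, modular rewiring, connectome) with their
canonical parameters (N = 100/200, T in {1,000, 10,000}, 10 repetitions,
uniform weights 0.15 / 0.1 / 0.08, theta = 0.1, alpha conventions); a
``scale`` factor shrinks N and the repetition count for cheaper runs but
never alpha or T unless explicitly overridden.
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import netmetrics
from .dynamics import simulate_var
from .infer import InferenceConfig, derive_seed, infer, infer_multivariate_te
from .netgen import (
    StructuralNetwork,
    assign_weights,
    make_modular,
    make_preferential_attachment,
    make_ws_ring,
    read_network,
    read_partition,
)

__all__ = ["ExperimentConfig", "run_experiment", "reproduce", "summarize"]


@dataclass
class ExperimentConfig:
    """Declarative description of one experiment.

    ``sweep`` optionally names a dotted field (e.g. ``topology.rewire_prob``)
    and the list of values to sweep over; one result row is produced per
    (sweep value x repetition x algorithm).
    """

    topology: dict
    weights: dict
    dynamics: dict
    inference: list[dict]
    n_repetitions: int = 1
    master_seed: int = 0
    sweep: dict | None = None
    macro: bool = True
    sigma_n_random: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ExperimentConfig":
        return cls(**json.loads(Path(path).read_text()))


def _set_dotted(cfg: ExperimentConfig, dotted: str, value) -> None:
    section, key = dotted.split(".", 1)
    getattr(cfg, section)[key] = value


def _build_network(topology: dict, seed: int) -> StructuralNetwork:
    kind = topology["type"]
    if kind == "ws":
        return make_ws_ring(
            topology["n_nodes"],
            topology.get("neighbors_per_side", 2),
            topology.get("rewire_prob", 0.0),
            rng_seed=seed,
        )
    if kind == "ba":
        return make_preferential_attachment(
            topology["n_nodes"], topology.get("links_per_new_node", 2), rng_seed=seed
        )
    if kind == "modular":
        return make_modular(
            topology["n_nodes"],
            topology.get("n_groups", 5),
            topology.get("out_degree", 10),
            topology.get("links_between_per_node", 0),
            rng_seed=seed,
        )
    if kind == "file":
        net = read_network(topology["path"], format=topology.get("format", "matrix"))
        if "partition_path" in topology:
            net.partition = read_partition(topology["partition_path"])
        return net
    raise ValueError(f"unknown topology type {kind!r}")


def _run_single(
    cfg: ExperimentConfig, rep: int, sweep_value
) -> list[dict]:
    work = copy.deepcopy(cfg)
    if cfg.sweep is not None:
        _set_dotted(work, cfg.sweep["field"], sweep_value)
    net_seed = derive_seed(cfg.master_seed, "network", rep)
    net = _build_network(work.topology, net_seed)
    coupling = assign_weights(
        net,
        cross_weight=work.weights.get("cross_weight"),
        incoming_total=work.weights.get("incoming_total"),
        self_weight=work.weights.get("self_weight", 0.0),
        theta=work.weights.get("theta", 0.1),
    )
    dyn = work.dynamics
    if dyn.get("model", "var") != "var":
        raise ValueError("run_experiment drives VAR dynamics; use the dynamics "
                         "module directly for neural mass simulations")
    ts = simulate_var(
        coupling,
        n_samples=dyn["n_samples"],
        burn_in=dyn.get("burn_in", 1000),
        rng_seed=derive_seed(cfg.master_seed, "dynamics", rep),
    )
    truth_macro = (
        netmetrics.macro_summary(
            net,
            partition=net.partition,
            sigma_n_random=work.sigma_n_random,
            rng_seed=derive_seed(cfg.master_seed, "sigma-truth", rep),
        )
        if work.macro
        else {}
    )
    rows = []
    for algo_spec in work.inference:
        icfg = InferenceConfig(
            algorithm=algo_spec["algorithm"],
            alpha=algo_spec.get("alpha", 0.01),
            max_lag_L=algo_spec.get("max_lag_L", 1),
            n_surrogates=algo_spec.get("n_surrogates", 500),
            prune=algo_spec.get("prune", True),
            seed=derive_seed(cfg.master_seed, "inference", rep, algo_spec["algorithm"]),
        )
        inferred = infer(ts, icfg)
        cm = netmetrics.confusion(inferred, net)
        row = {
            "repetition": rep,
            "sweep_value": sweep_value,
            "algorithm": icfg.algorithm,
            "n_nodes": net.n_nodes,
            "n_samples": ts.n_samples,
            "tp": cm.tp,
            "fp": cm.fp,
            "tn": cm.tn,
            "fn": cm.fn,
            "precision": cm.precision,
            "recall": cm.recall,
            "specificity": cm.specificity,
            "fpr": cm.fpr,
        }
        for k, v in truth_macro.items():
            row[f"truth_{k}"] = v
        if work.macro:
            inf_macro = netmetrics.macro_summary(
                inferred,
                partition=net.partition,
                sigma_n_random=work.sigma_n_random,
                rng_seed=derive_seed(
                    cfg.master_seed, "sigma-inf", rep, icfg.algorithm
                ),
            )
            for k, v in inf_macro.items():
                row[f"inferred_{k}"] = v
        rows.append(row)
    return rows


def run_experiment(
    cfg: ExperimentConfig, out_dir: str | Path | None = None
) -> pd.DataFrame:
    """Run all (sweep value x repetition x algorithm) cells and return one
    tidy row per cell; fully deterministic given the master seed."""
    sweep_values = cfg.sweep["values"] if cfg.sweep else [None]
    rows: list[dict] = []
    for value in sweep_values:
        for rep in range(cfg.n_repetitions):
            rows.extend(_run_single(cfg, rep, value))
    table = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "results.tsv", sep="\t", index=False)
        cfg.to_json(out_dir / "config.json")
    return table


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Mean performance and macro statistics per (sweep value, algorithm)."""
    keys = ["sweep_value", "algorithm"]
    numeric = table.select_dtypes("number").columns.difference(
        ["repetition", *keys]
    )
    return table.groupby(keys, dropna=False)[list(numeric)].mean().reset_index()


_ALL_ALGOS = [
    {"algorithm": "biv_mi"},
    {"algorithm": "biv_te"},
    {"algorithm": "multi_te"},
]


def reproduce(
    study: str,
    scale: float = 1.0,
    master_seed: int = 0,
    n_samples: int = 10000,
    connectome_path: str | None = None,
    sigma_n_random: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reproduce one validation study at a configurable scale.

    Returns the per-run results table and the per-condition summary.
    ``scale`` shrinks network size and repetitions, never alpha or T.
    """
    if not 0 < scale <= 1:
        raise ValueError("scale must lie in (0, 1]")
    reps = max(1, round(10 * scale))
    if study == "ws":
        n = max(6, round(100 * scale))
        grid = [0, 0.01, 0.05, 0.1, 0.2, 0.5, 1] if scale == 1 else [0, 0.5]
        cfg = ExperimentConfig(
            topology={"type": "ws", "n_nodes": n, "neighbors_per_side": 2},
            weights={"cross_weight": 0.15, "self_weight": 0.15, "theta": 0.1},
            dynamics={"model": "var", "n_samples": n_samples},
            inference=_ALL_ALGOS,
            n_repetitions=reps,
            master_seed=master_seed,
            sweep={"field": "topology.rewire_prob", "values": grid},
            sigma_n_random=sigma_n_random,
        )
    elif study == "scalefree":
        n = max(10, round(200 * scale))
        cfg = ExperimentConfig(
            topology={"type": "ba", "n_nodes": n, "links_per_new_node": 2},
            weights={"cross_weight": 0.1, "self_weight": 0.1, "theta": 0.1},
            dynamics={"model": "var", "n_samples": n_samples},
            inference=_ALL_ALGOS,
            n_repetitions=reps,
            master_seed=master_seed,
            sigma_n_random=sigma_n_random,
        )
    elif study == "modular":
        n_groups = 5
        group = max(4, round(20 * scale))
        out_deg = min(10, group - 1)
        grid = (
            [0, 2, 4, 6, 8, 10]
            if scale == 1
            else [0, out_deg // 2, out_deg]
        )
        cfg = ExperimentConfig(
            topology={
                "type": "modular",
                "n_nodes": n_groups * group,
                "n_groups": n_groups,
                "out_degree": out_deg,
            },
            weights={"cross_weight": 0.08, "self_weight": 0.08, "theta": 0.1},
            dynamics={"model": "var", "n_samples": n_samples},
            inference=_ALL_ALGOS,
            n_repetitions=reps,
            master_seed=master_seed,
            sweep={"field": "topology.links_between_per_node", "values": grid},
            sigma_n_random=sigma_n_random,
        )
    elif study == "connectome":
        if connectome_path is None:
            raise FileNotFoundError(
                "external data required: supply a weighted directed connectome "
                "adjacency matrix via connectome_path"
            )
        cfg = ExperimentConfig(
            topology={"type": "file", "path": connectome_path},
            weights={"incoming_total": 0.5, "self_weight": 0.2, "theta": 0.1},
            dynamics={"model": "var", "n_samples": n_samples},
            inference=_ALL_ALGOS,
            n_repetitions=reps,
            master_seed=master_seed,
            sweep={
                "field": "weights.incoming_total",
                "values": [0.3, 0.4, 0.5, 0.6, 0.7],
            },
            sigma_n_random=sigma_n_random,
        )
    else:
        raise ValueError(f"unknown study {study!r}")
    table = run_experiment(cfg, out_dir=out_dir)
    summary = summarize(table)
    if out_dir is not None:
        summary.to_csv(Path(out_dir) / "summary.tsv", sep="\t", index=False)
    return table, summary
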