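"""End-to-end pipeline: simulate -> network (linear / MI) -> topology ->
cluster -> promoter enrichment, with a declarative config and a manifest.

Every stage writes TSV outputs into the run directory; ``manifest.json``
records parameters, seeds and per-stage row counts so a run is reproducible
from its directory alone.  Identical config + seed gives identical outputs.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .datasets import (
    TernaryExpressionMatrix,
    write_network,
    write_modules,
    write_updown_tables,
)
from .linear import PearsonNetwork
from .minet import MutualInfoNetwork
from .modules import FagEC, MarkovClustering
from .synthetic import planted_block_truth, synth_expression
from .topology import topology_report


@dataclass
class RunConfig:
    """Declarative pipeline configuration; defaults mirror the reference
    study conditions (PCC threshold 0.9, max-MI fractions 0.8/0.9, module
    minimum size 6, 1000 bootstraps, fold tiers 2/3/4, hub degree 50)."""

    out_dir: str = "run"
    seed: int = 0
    # simulate stage
    n_genes: int = 120
    n_conditions: int = 100
    n_modules: int = 4
    module_size: int = 20
    flip_prob: float = 0.1
    # network stage
    network: str = "mknn"            # threshold | mknn | aracne_multiplicative | ...
    pcc_threshold: float = 0.9
    k: int = 10
    mi_fraction: float = 0.8
    mi_neighbors: int = 3
    # clustering stage
    cluster_algo: str = "fagec"       # fagec | mcl
    lam: float = 1.0
    inflation: float = 2.0
    min_size: int = 6
    # reporting
    hub_degree: int = 50
    log_level: str = "INFO"

    def validate(self) -> None:
        if not 0 < self.pcc_threshold <= 1:
            raise ValueError("pcc_threshold must be in (0, 1]")
        if not 0 < self.mi_fraction <= 1:
            raise ValueError("mi_fraction must be in (0, 1]")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")
        if self.min_size < 1:
            raise ValueError("min_size must be >= 1")
        if not 0 <= self.flip_prob < 0.5:
            raise ValueError("flip_prob must be in [0, 0.5)")


_LINEAR = ("threshold", "mknn")
_MI = ("aracne_multiplicative", "aracne_additive", "clr", "mrnet", "mi")


def run_pipeline(
    cfg: RunConfig, expression: TernaryExpressionMatrix | None = None
) -> dict:
    """Run simulate -> network -> topology -> cluster and write a manifest.

    When ``expression`` is given the simulate stage is skipped (resume from
    real data).  Returns the manifest dict.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": cfg.seed,
        "config": asdict(cfg),
        "stages": {},
    }

    if expression is None:
        truth = planted_block_truth(
            cfg.n_modules, cfg.module_size, cfg.n_conditions, cfg.flip_prob, cfg.seed
        )
        expression = synth_expression(cfg.n_genes, cfg.n_conditions, truth, cfg.seed + 1)
        write_updown_tables(expression, out / "conditions")
        manifest["stages"]["simulate"] = {
            "n_genes": expression.n_genes,
            "n_conditions": expression.n_conditions,
            "planted_modules": cfg.n_modules,
        }

    if cfg.network in _LINEAR:
        est = PearsonNetwork(
            method=cfg.network, threshold=cfg.pcc_threshold, k=cfg.k
        ).fit(expression)
    elif cfg.network in _MI:
        est = MutualInfoNetwork(
            algorithm=cfg.network,
            k_neighbors=cfg.mi_neighbors,
            fraction=cfg.mi_fraction,
            random_state=cfg.seed + 2,
        ).fit(expression)
    else:
        raise ValueError(f"unknown network method {cfg.network!r}")
    graph = est.graph_
    write_network(graph, out / "network.tsv")
    manifest["stages"]["network"] = {
        "method": cfg.network,
        "nodes": graph.number_of_nodes(),
        "edges": graph.number_of_edges(),
    }

    report = topology_report(graph, member_threshold=cfg.min_size)
    _write_tsv(
        out / "topology_nodes.tsv",
        ["gene", "degree", "clustering", "closeness", "betweenness",
         "topological_coefficient", "neighborhood_connectivity"],
        [
            (g, report.degree[g], report.clustering[g], report.closeness[g],
             report.betweenness[g], report.topological_coefficient[g],
             report.neighborhood_connectivity[g])
            for g in sorted(graph.nodes)
        ],
    )
    _write_tsv(out / "degree_dist.tsv", ["degree", "frequency"],
               sorted(report.degree_dist.items()))
    _write_tsv(out / "path_length_dist.tsv", ["length", "frequency"],
               sorted(report.path_length_dist.items()))
    manifest["stages"]["topology"] = {
        "density": report.density,
        "components": report.component_summary["n_components"],
        "main_component_nodes": report.component_summary["main_component_nodes"],
        "main_component_edges": report.component_summary["main_component_edges"],
        "powerlaw": list(report.powerlaw) if report.powerlaw else None,
    }

    if cfg.cluster_algo == "fagec":
        clu = FagEC(lam=cfg.lam, min_size=cfg.min_size).fit(graph)
    elif cfg.cluster_algo == "mcl":
        clu = MarkovClustering(inflation=cfg.inflation, min_size=cfg.min_size).fit(graph)
    else:
        raise ValueError(f"unknown cluster_algo {cfg.cluster_algo!r}")
    write_modules([sorted(m) for m in clu.modules_.modules], out / "modules.tsv")
    manifest["stages"]["cluster"] = {
        "algorithm": cfg.cluster_algo,
        "n_modules": len(clu.modules_),
        "sizes": clu.modules_.sizes,
    }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=_json_default)
    return manifest


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")


def _write_tsv(path: Path, header: list[str], rows) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(x) for x in row) + "\n")


def _fmt(x) -> str:
    if isinstance(x, float):
        return f"{x:.6g}"
    return str(x)
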