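"""End-to-end orchestration: filter -> cluster -> DE -> network -> subgraphs.

A :class:`PipelineConfig` collects every stage parameter; a single global
seed is fanned out deterministically to per-stage child seeds so the run is
reproducible as a whole and each stage is reproducible on its own.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, de, network, subgraph
from .expression import (
    ExpressionMatrix,
    FilterParams,
    filter_genes,
    log_transform,
    read_expression_matrix,
)
from .simulate import simulate_expression

__all__ = ["PipelineConfig", "validate_config", "run_pipeline"]

logger = logging.getLogger("scgenegroups")


@dataclass
class PipelineConfig:
    """All stage parameters of one pipeline run."""

    input: str | None = None                # path to expression matrix
    format: str = "dense_tsv"
    genes_file: str | None = None
    cells_file: str | None = None
    preset: str | None = None               # clusters | null | planted-modules
    log: str = "log2p1"                     # none | log2p1
    log_divisor: float = 1.0
    r_percent: float = 6.0
    c_percent: float = 50.0
    expression_threshold: float = 0.0
    sigma: float | str = "auto"
    knn_k: int = 15
    K: int | str = "auto"
    k_range: tuple[int, int] = (2, 10)
    fdr_threshold: float = 0.05
    g_percent: float | dict[int, float] = 1.8
    beta: int | str = "auto"
    n_select: int = 2
    window: int = 11
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        FilterParams(self.r_percent, self.c_percent, self.expression_threshold)
        if self.log not in ("none", "log2p1"):
            raise ValueError("log must be 'none' or 'log2p1'")
        if self.sigma != "auto" and float(self.sigma) <= 0:
            raise ValueError("sigma must be positive or 'auto'")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")
        if self.K != "auto" and int(self.K) < 2:
            raise ValueError("K must be >= 2 or 'auto'")
        lo, hi = self.k_range
        if not 2 <= lo <= hi:
            raise ValueError("k_range must satisfy 2 <= low <= high")
        if not 0 < self.fdr_threshold < 1:
            raise ValueError("fdr_threshold must lie in (0, 1)")
        for g in (
            self.g_percent.values()
            if isinstance(self.g_percent, dict)
            else [self.g_percent]
        ):
            if not 0 < g <= 100:
                raise ValueError("g_percent values must lie in (0, 100]")
        if self.beta != "auto" and int(self.beta) < 1:
            raise ValueError("beta must be >= 1 or 'auto'")
        if self.n_select < 1:
            raise ValueError("n_select must be >= 1")
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be a positive odd integer")
        if self.input is None and self.preset is None:
            raise ValueError("either input or preset must be given")


def validate_config(path) -> PipelineConfig:
    """Parse and range-check a YAML config file; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    if "k_range" in raw and isinstance(raw["k_range"], str):
        lo, hi = raw["k_range"].split(":")
        raw["k_range"] = (int(lo), int(hi))
    if "g_percent" in raw and isinstance(raw["g_percent"], dict):
        raw["g_percent"] = {int(k): float(v) for k, v in raw["g_percent"].items()}
    config = PipelineConfig(**raw)
    logger.info("config: %s", dataclasses.asdict(config))
    return config


def _child_seeds(seed: int, n: int) -> list[int]:
    """Stable per-stage seeds below 2**31 derived from one global seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


PRESETS = {
    "clusters": dict(
        n_cells=600, n_genes=2000, n_clusters=3, de_per_cluster=150,
        effect_size=3.0, modules=[(10, 3.0), (10, 3.0), (10, 3.0)],
    ),
    "null": dict(
        n_cells=200, n_genes=1000, n_clusters=1, de_per_cluster=0,
        effect_size=0.0, modules=[], n_background_programs=0,
    ),
}


def _load_input(config: PipelineConfig, seed: int):
    if config.preset is not None:
        if config.preset not in PRESETS:
            raise ValueError(f"unknown preset {config.preset!r}")
        matrix, truth = simulate_expression(seed=seed, **PRESETS[config.preset])
        return matrix, truth
    matrix = read_expression_matrix(
        config.input,
        format=config.format,
        genes_file=config.genes_file,
        cells_file=config.cells_file,
        transform_tag="raw_tpm" if config.log != "none" else "log",
    )
    return matrix, None


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in order and return (and optionally write) a
    machine-readable run summary.

    The summary records the chosen K, per-cluster DE counts, soft threshold
    beta, edge counts, and the detected subgraphs (label, eigenvector rank,
    size, density).  Clusters whose DE selection comes back empty are
    reported with ``n_de = 0`` and no network rather than failing.
    """
    seeds = _child_seeds(config.seed, 4)
    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    t0 = time.time()
    matrix, truth = _load_input(config, seeds[0])
    if config.log == "log2p1" and matrix.transform_tag == "raw_tpm":
        matrix = log_transform(matrix, config.log_divisor)
    params = FilterParams(
        config.r_percent, config.c_percent, config.expression_threshold
    )
    filtered = filter_genes(matrix, params)
    logger.info(
        "filtering: %d -> %d genes (%.1fs)",
        matrix.n_genes, filtered.n_genes, time.time() - t0,
    )

    t0 = time.time()
    sigma = None if config.sigma == "auto" else float(config.sigma)
    if config.K == "auto":
        assignment = clustering.choose_k_calinski_harabasz(
            filtered,
            range(config.k_range[0], config.k_range[1] + 1),
            sigma=sigma, k=config.knn_k, seed=seeds[1],
        )
    else:
        assignment = clustering.spectral_cluster(
            filtered, int(config.K), sigma=sigma, k=config.knn_k, seed=seeds[1]
        )
    logger.info("clustering: K=%d (%.1fs)", assignment.K, time.time() - t0)

    t0 = time.time()
    tables = de.select_de_genes(filtered, assignment, config.fdr_threshold)
    logger.info("DE selection (%.1fs)", time.time() - t0)

    summary: dict = {
        "seed": config.seed,
        "n_genes_input": int(matrix.n_genes),
        "n_genes_filtered": int(filtered.n_genes),
        "n_cells": int(matrix.n_cells),
        "K": int(assignment.K),
        "clusters": {},
    }
    if truth is not None and np.unique(truth.cell_labels).size > 1:
        summary["ari_vs_truth"] = clustering.adjusted_rand_index(
            truth.cell_labels, assignment.labels
        )

    for c, table in sorted(tables.items()):
        entry: dict = {"n_cells": int((assignment.labels == c).sum()),
                       "n_de": table.n_selected}
        if table.n_selected >= 3:
            g = (
                config.g_percent.get(c, 1.8)
                if isinstance(config.g_percent, dict)
                else config.g_percent
            )
            beta = None if config.beta == "auto" else int(config.beta)
            net = network.build_network(filtered, assignment, table, g, beta=beta)
            subs = subgraph.detect_gene_groups(
                net, config.n_select, config.window
            )
            entry.update(
                beta=net.beta,
                n_network_genes=int(net.n_genes),
                n_edges=net.edge_count,
                g_percent=float(g),
                subgraphs=[
                    {
                        "label": s.label,
                        "eigenvector": f"e{s.eigenvector_index}",
                        "size": s.size,
                        "density": s.density,
                        "genes": [str(g_) for g_ in s.member_genes],
                    }
                    for s in subs
                ],
            )
            if out_dir:
                network.write_edge_list(net, out_dir / f"network_cluster{c}.tsv")
        else:
            entry.update(subgraphs=[], note="too few DE genes for a network")
        summary["clusters"][str(c)] = entry

    if truth is not None and truth.module_genes:
        recovery = []
        for genes, c_truth in zip(truth.module_genes, truth.module_clusters):
            mask = truth.cell_labels == c_truth
            c_pipe = int(np.bincount(assignment.labels[mask]).argmax())
            subs = summary["clusters"][str(c_pipe)].get("subgraphs", [])
            module = set(map(str, genes))
            best = max(
                (
                    len(module & set(s["genes"])) / len(module | set(s["genes"]))
                    for s in subs
                ),
                default=0.0,
            )
            recovery.append(
                {
                    "module_cluster": int(c_truth),
                    "pipeline_cluster": c_pipe,
                    "jaccard": best,
                }
            )
        summary["module_recovery"] = recovery

    if out_dir:
        pd.DataFrame(
            {"cell_id": filtered.cell_ids, "cluster": assignment.labels}
        ).to_csv(out_dir / "labels.tsv", sep="\t", index=False)
        for c, table in sorted(tables.items()):
            table.to_dataframe().to_csv(
                out_dir / f"de_cluster{c}.tsv", sep="\t", index=False
            )
        (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
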