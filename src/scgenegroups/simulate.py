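"""Synthetic data with known ground truth for every pipeline stage.

:func:`simulate_expression` emulates the structure the pipeline assumes in
real scRNA-seq data: several cell subpopulations, subpopulation-specific
marker (DE) genes, and planted co-expressed gene modules driven by a shared
latent factor, all on a log-expression scale with dropout-like zeros.
:func:`simulate_planted_clique_graph` builds the classic planted-clique
benchmark for the dense-subgraph detector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .expression import LOG, ExpressionMatrix

__all__ = [
    "SimulationTruth",
    "simulate_expression",
    "simulate_planted_clique_graph",
]


@dataclass
class SimulationTruth:
    """Ground truth emitted alongside a simulated expression matrix."""

    cell_labels: np.ndarray                 # 1..n_clusters per cell
    de_genes: dict[int, np.ndarray]         # cluster -> marker gene ids
    module_genes: list[np.ndarray]          # planted co-expression modules
    module_clusters: list[int]              # cluster each module is planted in
    seed: int


def simulate_expression(
    n_cells: int = 600,
    n_genes: int = 2000,
    n_clusters: int = 3,
    de_per_cluster: int = 150,
    effect_size: float = 2.0,
    modules: list[tuple[int, float]] | None = None,
    seed: int = 0,
    background_mean_range: tuple[float, float] = (0.5, 4.0),
    marker_mean_range: tuple[float, float] = (0.3, 1.2),
    module_within_cluster: bool = True,
    n_background_programs: int = 1,
    program_strength: float = 0.6,
) -> tuple[ExpressionMatrix, SimulationTruth]:
    """Simulate a log-scale genes x cells matrix with known structure.

    Baseline log expression is ``Normal(mu_g, 1)`` with per-gene means
    drawn uniformly from ``background_mean_range``, clipped at zero so
    sub-detection values register as dropout-like zeros (giving each gene a
    realistic expressed fraction for the rare/ubiquitous filter to act on).
    Marker genes take their baseline mean from the lower
    ``marker_mean_range`` — subpopulation markers are near-silent outside
    their subpopulation — and are shifted up by ``effect_size`` log-units
    inside it.  Each ``(size, latent_strength)`` module is carved out of
    one cluster's marker set, its genes sharing a per-cell latent factor
    scaled by ``latent_strength`` so that they form a near-clique in
    correlation space.  With ``module_within_cluster`` (the default) the
    factor acts only on the cells of the module's own subpopulation — the
    co-regulation is a property of that subpopulation, so a module is
    invisible in the networks of the other clusters.  Deterministic for a
    given seed.

    Every gene additionally carries a weak loading on one of
    ``n_background_programs`` broad per-cell expression programs (library
    size, cell cycle and other shared covariates in real data).  This gives
    the co-expression background the diffuse, graded correlation structure
    of real transcriptomes; without it the topological-overlap ranking has
    nothing outside the planted modules to spend its edge budget on and
    binarization degenerates.
    """
    if modules is None:
        modules = []
    if n_cells < n_clusters or n_clusters < 1:
        raise ValueError("need at least one cell per cluster")
    if de_per_cluster * n_clusters > n_genes:
        raise ValueError("de_per_cluster * n_clusters exceeds n_genes")
    if modules and de_per_cluster == 0:
        raise ValueError("modules are planted inside marker sets; de_per_cluster is 0")
    for size, _ in modules:
        if size > de_per_cluster:
            raise ValueError("module size exceeds de_per_cluster")
    if len(modules) > n_clusters:
        raise ValueError("at most one module per cluster")

    rng = np.random.default_rng(seed)
    gene_ids = np.array([f"gene{i:05d}" for i in range(n_genes)], dtype=object)
    cell_ids = np.array([f"cell{i:05d}" for i in range(n_cells)], dtype=object)

    labels = 1 + (np.arange(n_cells) % n_clusters)
    mu = rng.uniform(*background_mean_range, size=n_genes)

    de_genes: dict[int, np.ndarray] = {}
    for c in range(1, n_clusters + 1):
        block = np.arange((c - 1) * de_per_cluster, c * de_per_cluster)
        de_genes[c] = gene_ids[block]
        mu[block] = rng.uniform(*marker_mean_range, size=block.size)

    values = mu[:, None] + rng.normal(0.0, 1.0, size=(n_genes, n_cells))
    module_rows = (
        np.concatenate(
            [
                np.arange(c0 * de_per_cluster, c0 * de_per_cluster + size)
                for m_idx, (size, _) in enumerate(modules)
                for c0 in [m_idx % n_clusters]
            ]
        )
        if modules
        else np.array([], dtype=int)
    )
    if n_background_programs > 0 and program_strength > 0:
        program_of = rng.integers(0, n_background_programs, size=n_genes)
        program_factors = rng.normal(0.0, 1.0, size=(n_background_programs, n_cells))
        loading = np.full(n_genes, program_strength)
        loading[module_rows] = 0.0  # module co-variation comes from its own factor
        values += loading[:, None] * program_factors[program_of]
    for c in range(1, n_clusters + 1):
        block = slice((c - 1) * de_per_cluster, c * de_per_cluster)
        values[block, labels == c] += effect_size

    module_gene_sets: list[np.ndarray] = []
    module_clusters: list[int] = []
    for m_idx, (size, strength) in enumerate(modules):
        c = (m_idx % n_clusters) + 1
        block = np.arange((c - 1) * de_per_cluster, (c - 1) * de_per_cluster + size)
        factor = rng.normal(0.0, 1.0, size=n_cells)
        if module_within_cluster:
            factor = factor * (labels == c)
        values[block] += strength * factor[None, :]
        module_gene_sets.append(gene_ids[block])
        module_clusters.append(c)

    values = np.maximum(values, 0.0)
    matrix = ExpressionMatrix(values, gene_ids, cell_ids, LOG)
    truth = SimulationTruth(labels, de_genes, module_gene_sets, module_clusters, seed)
    return matrix, truth


def simulate_planted_clique_graph(
    n_nodes: int, clique_size: int, background_p: float, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Erdos-Renyi G(n, p) background with a clique forced on a random subset.

    Returns a symmetric 0/1 adjacency with zero diagonal and the sorted
    member indices of the planted clique.
    """
    if clique_size > n_nodes:
        raise ValueError("clique_size cannot exceed n_nodes")
    if not 0 <= background_p < 1:
        raise ValueError("background_p must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    adj = np.zeros((n_nodes, n_nodes), dtype=int)
    ii, jj = np.triu_indices(n_nodes, k=1)
    edges = rng.random(ii.size) < background_p
    adj[ii[edges], jj[edges]] = 1
    members = np.sort(rng.choice(n_nodes, size=clique_size, replace=False))
    adj[np.ix_(members, members)] = 1
    adj = np.triu(adj, k=1)
    adj = adj + adj.T
    return adj, members
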