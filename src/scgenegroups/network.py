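"""Gene co-expression network construction per cell cluster.

From a cluster's DE genes: absolute Pearson correlation -> soft-thresholded
adjacency ``a_ij = |w_ij|^beta`` (beta chosen by the scale-free topology
criterion) -> topological overlap matrix (TOM) -> binary network keeping
the top g% of TOM values as edges.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats

from .clustering import ClusterAssignment
from .de import DEGeneTable
from .expression import ExpressionMatrix

__all__ = [
    "CoexpressionNetwork",
    "pearson_similarity",
    "select_soft_threshold",
    "tom_from_adjacency",
    "binarize_top_g",
    "build_network",
    "write_edge_list",
]


@dataclass
class CoexpressionNetwork:
    """All intermediate and final matrices of one cluster's network."""

    gene_ids: np.ndarray
    similarity: np.ndarray      # |Pearson|, zero diagonal
    beta: int
    adjacency: np.ndarray       # similarity ** beta, zero diagonal
    tom: np.ndarray             # topological overlap, diagonal 1 by convention
    g_percent: float
    binary: np.ndarray          # 0/1 edges, zero diagonal
    cluster_id: int | None = None

    @property
    def n_genes(self) -> int:
        return self.gene_ids.shape[0]

    @property
    def edge_count(self) -> int:
        return int(self.binary.sum()) // 2

    @property
    def degree_vector(self) -> np.ndarray:
        return self.binary.sum(axis=1).astype(int)


def pearson_similarity(m: ExpressionMatrix, genes=None, cells=None) -> np.ndarray:
    """Absolute pairwise Pearson correlation between genes, zero diagonal.

    ``genes``/``cells`` restrict to a subset (boolean mask or index array).
    Zero-variance genes make the correlation undefined and raise.
    """
    values = m.values
    gene_ids = m.gene_ids
    if genes is not None:
        values = values[genes]
        gene_ids = gene_ids[genes]
    if cells is not None:
        values = values[:, cells]
    if values.shape[1] < 3:
        raise ValueError("need at least 3 cells to correlate genes")
    flat = values.var(axis=1) == 0
    if flat.any():
        raise ValueError(
            f"zero-variance gene(s): {', '.join(map(str, gene_ids[flat][:10]))}"
        )
    w = np.abs(np.corrcoef(values))
    np.fill_diagonal(w, 0.0)
    return np.clip(w, 0.0, 1.0)


def _scale_free_fit(connectivity: np.ndarray, n_bins: int) -> float:
    """Signed R^2 of log10(freq) vs log10(k): the scale-free topology fit index.

    Positive-slope fits score 0 since a scale-free degree distribution
    requires frequency to fall with connectivity.
    """
    k = connectivity[connectivity > 0]
    if k.size < 2 or np.allclose(k, k[0]):
        return 0.0
    edges = np.geomspace(k.min(), k.max() + 1e-12, n_bins + 1)
    counts, _ = np.histogram(k, bins=edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    ok = counts > 0
    if ok.sum() < 3:
        return 0.0
    fit = scipy.stats.linregress(np.log10(centers[ok]), np.log10(counts[ok]))
    r2 = fit.rvalue**2
    return float(r2 if fit.slope < 0 else 0.0)


def select_soft_threshold(
    similarity: np.ndarray,
    candidates=range(1, 21),
    r2_target: float = 0.8,
    n_bins: int = 10,
    return_table: bool = False,
):
    """Pick the soft-threshold power by the scale-free topology criterion.

    For each candidate beta, the connectivity ``k_i = sum_j w_ij^beta`` is
    binned on a log scale and log-frequency is regressed on
    log-connectivity.  The smallest beta reaching ``r2_target`` wins; if
    none does, the beta with the best fit is returned.
    """
    candidates = sorted(set(int(b) for b in candidates))
    if not candidates:
        raise ValueError("candidate set is empty")
    rows = []
    for beta in candidates:
        k = (similarity**beta).sum(axis=1)
        if np.allclose(k, k[0] if k.size else 0.0):
            warnings.warn("degenerate connectivity (all equal); using smallest beta")
            chosen = candidates[0]
            if return_table:
                return chosen, pd.DataFrame(rows, columns=["beta", "r_squared"])
            return chosen
        rows.append((beta, _scale_free_fit(k, n_bins)))
    table = pd.DataFrame(rows, columns=["beta", "r_squared"])
    reaching = table[table.r_squared >= r2_target]
    chosen = int(reaching.beta.iloc[0]) if len(reaching) else int(
        table.beta.iloc[table.r_squared.idxmax()]
    )
    if return_table:
        return chosen, table
    return chosen


def soft_threshold(similarity: np.ndarray, beta: int) -> np.ndarray:
    """Adjacency ``a_ij = |w_ij|^beta`` with zero diagonal."""
    a = similarity**beta
    np.fill_diagonal(a, 0.0)
    return a


def tom_from_adjacency(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix.

    ``t_ij = (sum_m a_im a_mj + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` for
    i != j, where ``k_i`` is the connectivity of gene i; shared neighbours
    raise the overlap beyond the direct adjacency.  The diagonal is set to
    1 by convention.  The self-term exclusion in the sums is guaranteed by
    the zero diagonal of the adjacency.
    """
    a = np.asarray(adjacency, dtype=float)
    if a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if np.any(np.diag(a) != 0):
        raise ValueError("adjacency must have a zero diagonal")
    if np.any((a < 0) | (a > 1)):
        raise ValueError("adjacency entries must lie in [0, 1]")
    k = a.sum(axis=1)
    numerator = a @ a + a
    denominator = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(denominator > 0, numerator / denominator, 0.0)
    np.fill_diagonal(t, 1.0)
    return t


def binarize_top_g(tom: np.ndarray, g_percent: float):
    """Turn the top g% of off-diagonal TOM values into edges.

    The edge budget is ``round(g% * Z(Z-1)/200)`` (banker's rounding); ties
    at the cutoff are resolved by (row, column) lexicographic order of the
    upper-triangle pair so the result is bit-reproducible.

    Returns ``(binary, edge_count, degree_vector)``.
    """
    if not 0 < g_percent <= 100:
        raise ValueError("g_percent must lie in (0, 100]")
    z = tom.shape[0]
    n_pairs = z * (z - 1) // 2
    budget = round(g_percent * n_pairs / 100.0)
    if budget == 0:
        raise ValueError(
            f"g_percent={g_percent} with {z} genes yields an empty network"
        )
    ii, jj = np.triu_indices(z, k=1)
    vals = tom[ii, jj]
    top = np.lexsort((jj, ii, -vals))[:budget]
    binary = np.zeros((z, z), dtype=int)
    binary[ii[top], jj[top]] = 1
    binary |= binary.T
    return binary, int(budget), binary.sum(axis=1).astype(int)


def build_network(
    m: ExpressionMatrix,
    assignment: ClusterAssignment,
    de: DEGeneTable,
    g_percent: float,
    beta: int | None = None,
    beta_candidates=range(1, 21),
    r2_target: float = 0.8,
) -> CoexpressionNetwork:
    """Co-expression network over one cluster's selected DE genes.

    Composes |Pearson| similarity -> soft-threshold selection -> adjacency
    -> TOM -> top-g% binarization, using only the cluster's cells.
    Zero-variance genes within the cluster are dropped with a warning.
    """
    cells = assignment.labels == de.cluster_id
    gene_mask = np.isin(m.gene_ids, de.selected_genes)
    if not gene_mask.any():
        raise ValueError(f"no selected DE genes for cluster {de.cluster_id}")
    sub = m.values[gene_mask][:, cells]
    gene_ids = m.gene_ids[gene_mask]
    flat = sub.var(axis=1) == 0
    if flat.any():
        warnings.warn(
            f"dropping {int(flat.sum())} zero-variance gene(s) in cluster "
            f"{de.cluster_id}: {', '.join(map(str, gene_ids[flat][:5]))}"
        )
        sub = sub[~flat]
        gene_ids = gene_ids[~flat]
    if gene_ids.size < 3:
        raise ValueError(
            f"cluster {de.cluster_id}: fewer than 3 usable genes for a network"
        )
    w = np.abs(np.corrcoef(sub))
    np.fill_diagonal(w, 0.0)
    w = np.clip(w, 0.0, 1.0)
    if beta is None:
        beta = select_soft_threshold(w, beta_candidates, r2_target)
    adjacency = soft_threshold(w, beta)
    tom = tom_from_adjacency(adjacency)
    binary, _, _ = binarize_top_g(tom, g_percent)
    return CoexpressionNetwork(
        gene_ids, w, int(beta), adjacency, tom, float(g_percent), binary,
        cluster_id=de.cluster_id,
    )


def write_edge_list(net: CoexpressionNetwork, path, sidecar: bool = True) -> None:
    """TSV edge list (gene_a, gene_b, tom_value) plus a JSON parameter sidecar."""
    path = Path(path)
    ii, jj = np.nonzero(np.triu(net.binary, k=1))
    pd.DataFrame(
        {
            "gene_a": net.gene_ids[ii],
            "gene_b": net.gene_ids[jj],
            "tom_value": net.tom[ii, jj],
        }
    ).to_csv(path, sep="\t", index=False)
    if sidecar:
        meta = {
            "beta": net.beta,
            "g_percent": net.g_percent,
            "n_genes": int(net.n_genes),
            "n_edges": int(net.edge_count),
            "cluster_id": net.cluster_id,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))
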