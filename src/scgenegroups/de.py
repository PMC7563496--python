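"""Per-cluster differential-expression gene selection.

For each cluster, every gene is tested against every other cluster with a
two-sided Welch t-test.  The pairwise p-values of a gene are combined by
Holm-adjusting them and taking the middle-most adjusted value, so a gene
scores low only if it is differential in at least half of its comparisons.
Benjamini-Hochberg FDR is then applied across genes within the cluster and
genes below the FDR threshold (default 5%) are selected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .clustering import ClusterAssignment
from .expression import ExpressionMatrix

__all__ = [
    "DEGeneTable",
    "welch_t_pvalue",
    "combine_pvalues_middle_holm",
    "bh_fdr",
    "select_de_genes",
]


@dataclass
class DEGeneTable:
    """Combined p-value, BH FDR and selection flag per gene, for one cluster."""

    cluster_id: int
    gene_ids: np.ndarray
    combined_p: np.ndarray
    fdr: np.ndarray
    selected: np.ndarray
    fdr_threshold: float

    @property
    def selected_genes(self) -> np.ndarray:
        return self.gene_ids[self.selected]

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.gene_ids,
                "combined_p": self.combined_p,
                "fdr": self.fdr,
                "selected": self.selected,
            }
        )


def _welch_arrays(
    mean1, var1, n1, mean2, var2, n2
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Welch t statistic and two-sided p-value.

    Degenerate genes (zero variance in both groups) get p = 1 when the
    means agree and p -> 0 when they differ, so constants cannot produce
    NaNs downstream.
    """
    se2 = var1 / n1 + var2 / n2
    diff = mean1 - mean2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        df = se2**2 / (
            (var1 / n1) ** 2 / (n1 - 1) + (var2 / n2) ** 2 / (n2 - 1)
        )
        p = 2.0 * scipy.stats.t.sf(np.abs(t), df)
    degenerate = se2 == 0
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, np.where(diff == 0, 1.0, 0.0), p)
    return t, p


def welch_t_pvalue(x, y) -> tuple[float, float]:
    """Welch t-test of two samples: unequal variances, Welch-Satterthwaite
    degrees of freedom, two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    t, p = _welch_arrays(
        x.mean(), x.var(ddof=1), x.size, y.mean(), y.var(ddof=1), y.size
    )
    return float(t), float(p)


def holm_adjust(pvals: np.ndarray) -> np.ndarray:
    """Holm-Bonferroni step-down adjustment, returned in sorted (ascending) order."""
    p_sorted = np.sort(pvals)
    m = p_sorted.size
    adjusted = p_sorted * (m - np.arange(m))
    return np.minimum(np.maximum.accumulate(adjusted), 1.0)


def combine_pvalues_middle_holm(pvals) -> float:
    """Combine a gene's pairwise p-values: Holm-adjust, take the middle-most.

    For m values the ceil(m/2)-th smallest adjusted value is returned, so a
    low combined p requires differential expression in at least half of the
    pairwise comparisons.  A single p-value passes through unchanged.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("need a non-empty 1-D vector of p-values")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    adjusted = holm_adjust(p)
    return float(adjusted[math.ceil(p.size / 2) - 1])


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, mapped back to input order."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(q_sorted[::-1])[::-1], 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def _cluster_stats(values: np.ndarray, labels: np.ndarray, cluster: int):
    cols = labels == cluster
    sub = values[:, cols]
    return sub.mean(axis=1), sub.var(axis=1, ddof=1), int(cols.sum())


def select_de_genes(
    m: ExpressionMatrix,
    assignment: ClusterAssignment,
    fdr_threshold: float = 0.05,
) -> dict[int, DEGeneTable]:
    """Differential-expression tables, one per cluster.

    For cluster c, each gene is Welch-tested against every other cluster,
    the pairwise p-values are combined via the Holm middle-most rule, BH is
    applied across genes, and genes with FDR below the threshold are
    flagged as selected.
    """
    labels = assignment.labels
    clusters = np.unique(labels)
    if clusters.size < 2:
        raise ValueError("need at least 2 clusters for pairwise comparisons")
    sizes = {int(c): int((labels == c).sum()) for c in clusters}
    small = [c for c, n in sizes.items() if n < 2]
    if small:
        raise ValueError(f"cluster(s) {small} have fewer than 2 cells")
    stats = {int(c): _cluster_stats(m.values, labels, c) for c in clusters}

    tables: dict[int, DEGeneTable] = {}
    for c in map(int, clusters):
        mean_c, var_c, n_c = stats[c]
        pair_p = np.column_stack(
            [
                _welch_arrays(mean_c, var_c, n_c, *stats[int(o)])[1]
                for o in clusters
                if int(o) != c
            ]
        )
        combined = np.apply_along_axis(combine_pvalues_middle_holm, 1, pair_p)
        fdr = bh_fdr(combined)
        selected = fdr < fdr_threshold
        tables[c] = DEGeneTable(
            c, m.gene_ids, combined, fdr, selected, fdr_threshold
        )
    return tables
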