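"""Expression-matrix I/O, log transformation, and gene filtering.

The container here is a genes x cells matrix of expression values, either
raw TPM or log-scale (``log2(TPM/divisor + 1)``).  Filtering removes three
kinds of uninformative genes before clustering:

* *rare* genes, expressed in fewer than r% of cells;
* *ubiquitous* genes, expressed in at least (100 - r)% of cells;
* *invariable* genes, i.e. everything outside the most variable c% after
  controlling for the mean-variability relationship.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "ExpressionMatrix",
    "FilterParams",
    "ExpressionIOError",
    "read_expression_matrix",
    "write_expression_matrix",
    "log_transform",
    "filter_rare_ubiquitous",
    "select_variable_genes",
]

RAW_TPM = "raw_tpm"
LOG = "log"


class ExpressionIOError(ValueError):
    """Malformed expression-matrix file."""


def _check_unique(ids: np.ndarray, kind: str) -> None:
    uniq, counts = np.unique(ids, return_counts=True)
    dups = uniq[counts > 1]
    if dups.size:
        raise ValueError(f"duplicate {kind} ids: {', '.join(map(str, dups[:10]))}")


@dataclass
class ExpressionMatrix:
    """A genes x cells expression matrix with identifiers.

    Parameters
    ----------
    values
        Dense array of shape ``(n_genes, n_cells)``.
    gene_ids, cell_ids
        Unique, ordered identifiers matching the rows / columns.
    transform_tag
        ``"raw_tpm"`` for linear-scale values, ``"log"`` after the log
        transform.  Raw values must be finite and non-negative.
    """

    values: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    transform_tag: str = RAW_TPM

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x cells array")
        if self.gene_ids.shape[0] != self.values.shape[0]:
            raise ValueError("gene_ids length must equal the number of rows")
        if self.cell_ids.shape[0] != self.values.shape[1]:
            raise ValueError("cell_ids length must equal the number of columns")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if self.transform_tag not in (RAW_TPM, LOG):
            raise ValueError(f"unknown transform_tag {self.transform_tag!r}")
        if self.transform_tag == RAW_TPM and np.any(self.values < 0):
            raise ValueError("raw TPM values must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, mask_or_index) -> "ExpressionMatrix":
        """Restrict to a subset of genes, preserving order and values."""
        return ExpressionMatrix(
            self.values[mask_or_index],
            self.gene_ids[mask_or_index],
            self.cell_ids,
            self.transform_tag,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


@dataclass
class FilterParams:
    """Parameters for rare/ubiquitous/invariable gene filtering.

    ``r_percent`` is the rare/ubiquitous cutoff: keep genes expressed in at
    least r% and in fewer than (100 - r)% of cells.  ``c_percent`` is the
    fraction of most-variable genes to keep.  A gene counts as expressed in
    a cell when its value exceeds ``expression_threshold``.
    """

    r_percent: float = 6.0
    c_percent: float = 50.0
    expression_threshold: float = 0.0
    n_bins: int = 20

    def __post_init__(self) -> None:
        if not 0 < self.r_percent < 50:
            raise ValueError("r_percent must lie in (0, 50)")
        if not 0 < self.c_percent <= 100:
            raise ValueError("c_percent must lie in (0, 100]")
        if self.expression_threshold < 0:
            raise ValueError("expression_threshold must be >= 0")


def read_expression_matrix(
    path,
    format: str = "dense_tsv",
    genes_file=None,
    cells_file=None,
    transform_tag: str = RAW_TPM,
    sep: str = "\t",
) -> ExpressionMatrix:
    """Read a genes x cells matrix from disk.

    ``dense_tsv``: first column holds gene identifiers, the header row holds
    cell identifiers.  ``matrix_market``: a triplet ``.mtx`` file with genes
    as rows, accompanied by one-id-per-line ``genes_file`` and ``cells_file``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "dense_tsv":
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except pd.errors.EmptyDataError as exc:
            raise ExpressionIOError(f"{path}: file is empty or has no header") from exc
        except (pd.errors.ParserError, ValueError) as exc:
            raise ExpressionIOError(f"{path}: {exc}") from exc
        if df.shape[1] == 0:
            raise ExpressionIOError(f"{path}: no cell columns found")
        if not np.issubdtype(df.to_numpy().dtype, np.number):
            bad = df.columns[[not np.issubdtype(d, np.number) for d in df.dtypes]]
            raise ExpressionIOError(
                f"{path}: non-numeric values in columns {list(bad[:5])}"
            )
        return ExpressionMatrix(
            df.to_numpy(dtype=float),
            df.index.to_numpy(dtype=object),
            df.columns.to_numpy(dtype=object),
            transform_tag,
        )
    if format == "matrix_market":
        if genes_file is None or cells_file is None:
            raise ValueError("matrix_market format requires genes_file and cells_file")
        try:
            mat = scipy.io.mmread(path)
        except ValueError as exc:
            raise ExpressionIOError(f"{path}: {exc}") from exc
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        genes = np.loadtxt(genes_file, dtype=str, ndmin=1).astype(object)
        cells = np.loadtxt(cells_file, dtype=str, ndmin=1).astype(object)
        return ExpressionMatrix(np.asarray(mat, dtype=float), genes, cells, transform_tag)
    raise ValueError(f"unknown format {format!r}")


def write_expression_matrix(m: ExpressionMatrix, path, sep: str = "\t") -> None:
    """Write in the dense TSV layout that :func:`read_expression_matrix` reads."""
    m.to_dataframe().to_csv(path, sep=sep)


def log_transform(m: ExpressionMatrix, divisor: float = 1.0) -> ExpressionMatrix:
    """Apply ``log2(v / divisor + 1)`` to a raw-TPM matrix.

    ``divisor`` accommodates datasets whose published convention is
    ``log2(TPM/10 + 1)``; the default keeps plain ``log2(TPM + 1)``.
    """
    if m.transform_tag == LOG:
        raise ValueError("matrix is already log-transformed")
    if divisor <= 0:
        raise ValueError("divisor must be positive")
    return ExpressionMatrix(
        np.log2(m.values / divisor + 1.0), m.gene_ids, m.cell_ids, LOG
    )


def expressed_fraction(m: ExpressionMatrix, threshold: float = 0.0) -> np.ndarray:
    """Per-gene fraction of cells with value above ``threshold``."""
    return (m.values > threshold).mean(axis=1)


def filter_rare_ubiquitous(m: ExpressionMatrix, params: FilterParams | None = None) -> ExpressionMatrix:
    """Drop genes expressed in fewer than r% or in at least (100 - r)% of cells."""
    params = params or FilterParams()
    if m.n_cells < 1:
        raise ValueError("matrix has no cells")
    pct = 100.0 * expressed_fraction(m, params.expression_threshold)
    keep = (pct >= params.r_percent) & (pct < 100.0 - params.r_percent)
    if not keep.any():
        raise ValueError(
            "rare/ubiquitous filtering removed every gene; "
            "lower r_percent or adjust expression_threshold"
        )
    return m.subset_genes(keep)


def variability_residuals(m: ExpressionMatrix, n_bins: int = 20) -> np.ndarray:
    """Mean-controlled variability score per gene.

    Genes are grouped into ``n_bins`` equal-count bins by mean log
    expression; the score is the gene's variance minus the median variance
    of its bin, so a high score means more variable than genes of similar
    abundance.
    """
    means = m.values.mean(axis=1)
    variances = m.values.var(axis=1, ddof=1) if m.n_cells > 1 else np.zeros(m.n_genes)
    order = np.argsort(means, kind="stable")
    residual = np.empty(m.n_genes)
    for chunk in np.array_split(order, min(n_bins, m.n_genes)):
        residual[chunk] = variances[chunk] - np.median(variances[chunk])
    return residual


def select_variable_genes(m: ExpressionMatrix, params: FilterParams | None = None) -> ExpressionMatrix:
    """Keep the most variable c% of genes after the mean-variability trend fit."""
    params = params or FilterParams()
    if m.transform_tag != LOG:
        raise ValueError("variable-gene selection expects a log-transformed matrix")
    if m.n_genes < 10:
        raise ValueError("need at least 10 genes for variable-gene selection")
    n_keep = int(round(params.c_percent * m.n_genes / 100.0))
    if n_keep < 2:
        raise ValueError(
            f"c_percent={params.c_percent} keeps {n_keep} gene(s); need at least 2"
        )
    if n_keep >= m.n_genes:
        return m
    residual = variability_residuals(m, params.n_bins)
    # stable sort on negated residuals keeps input order among ties
    ranked = np.argsort(-residual, kind="stable")[:n_keep]
    keep = np.zeros(m.n_genes, dtype=bool)
    keep[ranked] = True
    return m.subset_genes(keep)


def filter_genes(m: ExpressionMatrix, params: FilterParams | None = None) -> ExpressionMatrix:
    """Full filtering stage: rare/ubiquitous first, then variable-gene selection."""
    params = params or FilterParams()
    out = filter_rare_ubiquitous(m, params)
    if out.n_genes < 10:
        warnings.warn(
            f"only {out.n_genes} genes survive rare/ubiquitous filtering; "
            "skipping variable-gene selection"
        )
        return out
    return select_variable_genes(out, params)
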