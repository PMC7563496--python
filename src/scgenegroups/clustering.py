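"""Spectral clustering of cells and partition evaluation.

Cells are points in gene space.  A Gaussian-kernel similarity graph is
sparsified to the union k-nearest-neighbour graph, the graph Laplacian
``L = D - S`` is eigendecomposed, and K-means runs in the space spanned by
the K smallest eigenvectors.  The number of clusters is chosen by the
Calinski-Harabasz index; partitions are compared with the adjusted Rand
index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, calinski_harabasz_score

from .expression import ExpressionMatrix

__all__ = [
    "SimilarityGraph",
    "ClusterAssignment",
    "gaussian_knn_similarity",
    "laplacian",
    "spectral_embed",
    "kmeans_assign",
    "spectral_cluster",
    "choose_k_calinski_harabasz",
    "adjusted_rand_index",
]


@dataclass
class SimilarityGraph:
    """Symmetric kNN-sparsified Gaussian similarity over cells."""

    weights: np.ndarray
    kernel_sigma: float
    knn_k: int

    @property
    def degree(self) -> np.ndarray:
        return self.weights.sum(axis=1)


@dataclass
class ClusterAssignment:
    """Per-cell labels in {1..K} plus the spectral embedding that produced them."""

    labels: np.ndarray
    K: int
    embedding: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        present = np.unique(self.labels)
        if not np.array_equal(present, np.arange(1, self.K + 1)):
            raise ValueError("labels must cover {1..K} with every cluster non-empty")
        if self.embedding.shape != (self.labels.shape[0], self.K):
            raise ValueError("embedding must be cells x K")


def gaussian_knn_similarity(
    m: ExpressionMatrix, sigma: float | None = None, k: int = 15
) -> SimilarityGraph:
    """Gaussian-kernel similarity between cells, kept only on kNN pairs.

    ``s_ij = exp(-||x_i - x_j||^2 / (2 sigma^2))`` when i and j are mutual
    or one-sided k-nearest neighbours (union rule), zero otherwise, with a
    zero diagonal.  When ``sigma`` is None it defaults to the median
    distance over the retained neighbour pairs.
    """
    n = m.n_cells
    if n < 2:
        raise ValueError("need at least 2 cells")
    if not 0 < k < n:
        raise ValueError(f"k must satisfy 0 < k < n_cells (got k={k}, n={n})")
    if sigma is not None and sigma <= 0:
        raise ValueError("sigma must be positive")
    X = m.values.T  # cells x genes
    dist = squareform(pdist(X))
    # k nearest excluding self, then symmetrize by the union (OR) rule
    nn = np.argsort(dist + np.diag(np.full(n, np.inf)), axis=1, kind="stable")[:, :k]
    mask = np.zeros((n, n), dtype=bool)
    mask[np.repeat(np.arange(n), k), nn.ravel()] = True
    mask |= mask.T
    np.fill_diagonal(mask, False)
    if sigma is None:
        sigma = float(np.median(dist[mask]))
        if sigma <= 0:
            sigma = 1.0  # all retained pairs coincide; kernel value is 1 anyway
    weights = np.zeros((n, n))
    weights[mask] = np.exp(-dist[mask] ** 2 / (2.0 * sigma**2))
    return SimilarityGraph(weights, float(sigma), k)


def laplacian(g: SimilarityGraph, normalized: bool = False) -> np.ndarray:
    """Graph Laplacian ``L = D - S`` (default) or its symmetric normalization.

    The unnormalized form matches the construction used throughout this
    package; ``normalized=True`` returns ``D^{-1/2} L D^{-1/2}`` with
    isolated vertices left untouched.
    """
    S = g.weights
    d = S.sum(axis=1)
    L = np.diag(d) - S
    if normalized:
        with np.errstate(divide="ignore"):
            inv_sqrt = np.where(d > 0, 1.0 / np.sqrt(np.where(d > 0, d, 1.0)), 0.0)
        L = inv_sqrt[:, None] * L * inv_sqrt[None, :]
    return L


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive."""
    idx = np.argmax(np.abs(vectors), axis=0)
    signs = np.sign(vectors[idx, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return vectors * signs


def spectral_embed(L: np.ndarray, K: int) -> np.ndarray:
    """Columns are unit-norm eigenvectors of the K smallest eigenvalues of L."""
    n = L.shape[0]
    if not 0 < K < n:
        raise ValueError("K must satisfy 0 < K < n_cells")
    vals, vecs = np.linalg.eigh(L)
    return _fix_signs(vecs[:, :K])


def kmeans_assign(embedding: np.ndarray, K: int, seed: int = 0) -> ClusterAssignment:
    """K-means in embedding space; 20 restarts, labels renumbered to 1..K."""
    if K < 2:
        raise ValueError("K must be >= 2")
    km = KMeans(n_clusters=K, n_init=20, random_state=seed)
    labels = km.fit_predict(embedding) + 1
    # degenerate inputs (e.g. all points identical) can leave clusters empty;
    # any labeling is acceptable there, so fill them deterministically
    for lab in np.setdiff1d(np.arange(1, K + 1), labels):
        donor = np.argmax(np.bincount(labels, minlength=K + 1)[1:]) + 1
        labels[np.flatnonzero(labels == donor)[0]] = lab
    return ClusterAssignment(labels, K, embedding)


def spectral_cluster(
    m: ExpressionMatrix,
    K: int,
    sigma: float | None = None,
    k: int = 15,
    seed: int = 0,
    normalized: bool = False,
) -> ClusterAssignment:
    """Full two-step spectral clustering: embed by the Laplacian, then K-means."""
    g = gaussian_knn_similarity(m, sigma=sigma, k=k)
    emb = spectral_embed(laplacian(g, normalized=normalized), K)
    return kmeans_assign(emb, K, seed)


def choose_k_calinski_harabasz(
    m: ExpressionMatrix,
    k_range=range(2, 11),
    sigma: float | None = None,
    k: int = 15,
    seed: int = 0,
    normalized: bool = False,
    return_scores: bool = False,
):
    """Run spectral clustering for each candidate K and keep the partition
    with the highest Calinski-Harabasz index on its own embedding."""
    candidates = sorted(set(int(c) for c in k_range))
    if not candidates:
        raise ValueError("k_range is empty")
    if candidates[0] < 2 or candidates[-1] >= m.n_cells:
        raise ValueError("k_range must lie within [2, n_cells - 1]")
    g = gaussian_knn_similarity(m, sigma=sigma, k=k)
    L = laplacian(g, normalized=normalized)
    best, best_score, scores = None, -np.inf, {}
    for K in candidates:
        emb = spectral_embed(L, K)
        assignment = kmeans_assign(emb, K, seed)
        if len(candidates) == 1:
            best = assignment
            break
        try:
            score = calinski_harabasz_score(emb, assignment.labels)
        except ValueError:
            score = -np.inf  # single effective cluster in the embedding
        scores[K] = score
        if score > best_score:
            best, best_score = assignment, score
    if return_scores:
        return best, scores
    return best


def adjusted_rand_index(a, b) -> float:
    """Chance-corrected agreement between two labelings of the same cells."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("labelings must have equal length")
    return float(adjusted_rand_score(a, b))
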