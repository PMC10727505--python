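"""Exact full-matrix backend: correlation matrices as a single matrix product.

Serves as the exact oracle for the index-based search backend, and provides
the sizing helpers used to decide when the full matrix no longer fits in
memory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .edges import EdgeList, canonical_edges, recompute_values, top_k_edges
from .projections import FeatureMatrix, project_correlation

__all__ = [
    "CorrelationMatrix",
    "full_correlation_matrix",
    "topk_from_matrix",
    "threshold_from_matrix",
    "count_pairs",
    "estimate_full_matrix_memory_gb",
]


@dataclass
class CorrelationMatrix:
    values: np.ndarray  # n x n, symmetric, unit diagonal
    feature_names: list[str]
    method: str

    @property
    def n_features(self) -> int:
        return self.values.shape[0]


def _gram(projected: np.ndarray) -> np.ndarray:
    C = projected.T @ projected
    C = np.clip((C + C.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return C


def full_correlation_matrix(X: FeatureMatrix, method: str = "pearson") -> CorrelationMatrix:
    """All pairwise correlations via the Gram product of projected columns."""
    P = project_correlation(X, method)
    return CorrelationMatrix(_gram(P.values), feature_names=list(X.feature_names), method=method)


def _upper_triangle_edges(C: np.ndarray, feature_names, ranking: str) -> EdgeList:
    iu, ju = np.triu_indices(C.shape[0], k=1)
    return canonical_edges(iu, ju, C[iu, ju], feature_names, ranking=ranking)


def topk_from_matrix(
    X: FeatureMatrix, k: int, ranking: str = "abs", method: str = "pearson"
) -> EdgeList:
    """Exact top-k feature pairs from the full correlation matrix.

    Sorted by the ranking key descending, ties broken by ascending (i, j);
    this ordering is the reference contract for the index backend.
    """
    n = X.n_features
    total = count_pairs(n)
    if not 1 <= k <= total:
        raise ValueError(f"k must be in [1, {total}] for n={n} features, got {k}")
    P = project_correlation(X, method)
    C = _gram(P.values)
    edges = top_k_edges(_upper_triangle_edges(C, X.feature_names, ranking), k)
    return recompute_values(edges, P.values)


def threshold_from_matrix(
    X: FeatureMatrix, t: float, ranking: str = "abs", method: str = "pearson"
) -> EdgeList:
    """All pairs with |r| >= t (ranking="abs") or r >= t (ranking="signed")."""
    if not 0.0 < t <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {t}")
    P = project_correlation(X, method)
    C = _gram(P.values)
    edges = _upper_triangle_edges(C, X.feature_names, ranking)
    key = np.abs(edges.value) if ranking == "abs" else edges.value
    keep = key >= t
    edges = EdgeList(
        edges.i[keep], edges.j[keep], edges.value[keep], edges.feature_names, ranking=ranking
    )
    return recompute_values(edges, P.values)


def count_pairs(n: int) -> int:
    """Number of distinct unordered feature pairs, n * (n - 1) / 2."""
    n = int(n)
    if n < 0:
        raise ValueError("n must be non-negative")
    return n * (n - 1) // 2


def estimate_full_matrix_memory_gb(n: int) -> float:
    """Memory of an n x n float64 correlation matrix in GB: 64 * n^2 / (8e9)."""
    n = int(n)
    if n < 0:
        raise ValueError("n must be non-negative")
    return 64.0 * n * n / 8e9
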