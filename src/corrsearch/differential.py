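"""Differential correlation discovery across two conditions.

The difference ``cor(x1, y1) - cor(x2, y2)`` for every feature pair equals a
single scalar product in the paired delta/kappa representation, so both the
full difference matrix and the approximate top-k search reuse the machinery
of the correlation case: a joint ball tree over delta(X) and -delta(X) is
queried with the kappa(x) vectors, and the difference is recovered from the
distance d as ``sign * (2 - d^2 / 2)``.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
from sklearn.neighbors import BallTree

from .edges import recompute_values, symmetrize, top_k_edges
from .matrix import CorrelationMatrix, count_pairs, full_correlation_matrix
from .projections import FeatureMatrix, project_differential
from .search import MetricIndex, SearchConfig, _assemble, _run_batches

__all__ = [
    "full_differential_matrix",
    "topk_differential_search",
    "differential_edge_frequency",
]

logger = logging.getLogger(__name__)

_MAX_DIFF_DIST = 2.0 * np.sqrt(2.0)


def full_differential_matrix(
    X1: FeatureMatrix, X2: FeatureMatrix, method: str = "pearson"
) -> CorrelationMatrix:
    """Exact difference of the two conditions' correlation matrices."""
    if X1.feature_names != X2.feature_names:
        raise ValueError("the two conditions must share identical feature names in order")
    C1 = full_correlation_matrix(X1, method)
    C2 = full_correlation_matrix(X2, method)
    D = C1.values - C2.values
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return CorrelationMatrix(D, feature_names=list(X1.feature_names), method=method)


def _diff_knn_batch(index: MetricIndex, queries: np.ndarray, query_ids: np.ndarray,
                    k_prime: int, dualtree: bool):
    dist, idx = index.tree.query(queries, k=k_prime, dualtree=dualtree)
    assert dist.max(initial=0.0) <= _MAX_DIFF_DIST + 1e-9
    feature, sign = index.origin(idx.ravel())
    qid = np.repeat(query_ids, k_prime)
    value = sign * (2.0 - dist.ravel() ** 2 / 2.0)
    keep = feature != qid
    return qid[keep], feature[keep], np.clip(value[keep], -2.0, 2.0)


def topk_differential_search(
    X1: FeatureMatrix,
    X2: FeatureMatrix,
    k: int,
    config: Optional[SearchConfig] = None,
    method: str = "pearson",
) -> EdgeList:
    """Approximate top-k correlation *differences* between two conditions.

    Contracts (approximation factor, batching, merging, ordering) are the
    same as for :func:`corrsearch.search.topk_correlation_search`; ranking is
    by absolute difference by default.  Exhaustive approximation factors make
    the result exact with respect to :func:`full_differential_matrix`.
    """
    from .search import resolve_k_prime  # local import keeps module deps one-way

    config = config or SearchConfig()
    n = X1.n_features
    total = count_pairs(n)
    if not 1 <= k <= total:
        raise ValueError(f"k must be in [1, {total}] for n={n} features, got {k}")
    rep = project_differential(X1, X2, method)
    points = np.vstack([rep.delta.T, -rep.delta.T])
    index = MetricIndex(BallTree(points), n_features=n, feature_names=list(rep.feature_names))
    k_prime = resolve_k_prime(k, n, config.approximation_factor)
    logger.info(
        "differential top-k: n=%d m1=%d m2=%d k=%d a=%g k'=%d",
        n, rep.m1, rep.m2, k, config.approximation_factor, k_prime,
    )
    queries = rep.kappa.T

    def worker(ix, q, qids):
        return _diff_knn_batch(ix, q, qids, k_prime, config.dualtree)

    parts = _run_batches(index, queries, config, worker)
    edges = top_k_edges(_assemble(parts, rep.feature_names, config.ranking), k)
    edges = recompute_values(edges, rep.delta, rep.kappa, clip=2.0)
    return symmetrize(edges) if config.symmetrize else edges


def differential_edge_frequency(
    X1: FeatureMatrix,
    X2: FeatureMatrix,
    k: int,
    n_bootstrap: int,
    seed: int,
    config: Optional[SearchConfig] = None,
    method: str = "pearson",
):
    """Per-edge selection frequency over sample bootstraps within each condition.

    Repeats the top-k differential search ``n_bootstrap`` times on resampled
    (with replacement) rows of X1 and X2 and reports, for every edge ever
    selected, the fraction of replicates in which it appeared.  Returns a list
    of ((i, j), frequency) sorted by frequency descending then pair.
    """
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be >= 1")
    rng = np.random.default_rng(seed)
    counts: dict[tuple[int, int], int] = {}
    for _ in range(n_bootstrap):
        rows1 = rng.integers(0, X1.n_samples, X1.n_samples)
        rows2 = rng.integers(0, X2.n_samples, X2.n_samples)
        B1 = FeatureMatrix(X1.values[rows1], feature_names=list(X1.feature_names))
        B2 = FeatureMatrix(X2.values[rows2], feature_names=list(X2.feature_names))
        edges = topk_differential_search(B1, B2, k, config, method)
        for pair in edges.pair_set():
            counts[pair] = counts.get(pair, 0) + 1
    items = [(pair, c / n_bootstrap) for pair, c in counts.items()]
    items.sort(key=lambda x: (-x[1], x[0]))
    return items
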