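"""Approximate top-k / exact threshold correlation search via joint metric indexing.

A ball tree is built over the projected feature vectors *and* their negations
(2n points), so that nearest-neighbor queries retrieve the strongest
correlations of either sign: the correlation is recovered from the Euclidean
distance d to a matched point as ``sign * (1 - d^2 / 2)``.

Top-k search is approximate: each query feature retrieves only
``k' = ceil(a * k / n)`` candidates (``a`` is the approximation factor) and the
per-query results are merged, deduplicated and partitioned to the global
top-k.  Radius (threshold) queries are exact.  The code path never allocates
an n x n matrix.
"""

from __future__ import annotations

import logging
import math
import os
import tempfile
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from joblib import Parallel, delayed
from sklearn.neighbors import BallTree

from .edges import EdgeList, canonical_edges, recompute_values, top_k_edges
from .edges import symmetrize as symmetrize  # re-export: search-level post-processing
from .matrix import count_pairs, topk_from_matrix
from .projections import FeatureMatrix, ProjectedMatrix, corr_to_distance, project_correlation

__all__ = [
    "MetricIndex",
    "SearchConfig",
    "build_joint_index",
    "topk_correlation_search",
    "threshold_correlation_search",
    "merge_batch_results",
    "symmetrize",
    "empirical_sensitivity",
    "resolve_k_prime",
]

logger = logging.getLogger(__name__)


@dataclass
class SearchConfig:
    """Knobs for the index-based search backend.

    approximation_factor : a >= 1; each query retrieves k' = ceil(a * k / n)
        candidates (capped at the 2n indexed points).  Larger a -> higher
        sensitivity, more work.  At k' >= 2n the search is exhaustive/exact.
    batch_size : queries per batch (None = single batch).
    n_workers : parallel workers over batches (threads; BallTree releases the GIL).
    ranking : "abs" ranks by |value|, "signed" by the value itself.
    symmetrize : also emit (j, i) for every (i, j) in the final result.
    dualtree : use the dual-tree query optimization (identical results).
    low_memory : spill per-batch results to temporary files before merging.
    seed : recorded for provenance; the search itself is deterministic.
    """

    approximation_factor: float = 10.0
    batch_size: Optional[int] = None
    n_workers: int = 1
    ranking: str = "abs"
    symmetrize: bool = False
    dualtree: bool = False
    low_memory: bool = False
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.approximation_factor < 1:
            raise ValueError("approximation factor must be >= 1")
        if self.batch_size is not None and self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.n_workers < 1:
            raise ValueError("n_workers must be >= 1")


@dataclass
class MetricIndex:
    """Exact Euclidean index over the 2n joint +/- projected feature vectors."""

    tree: BallTree
    n_features: int
    feature_names: list[str]

    def origin(self, point_index: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map indexed point ids to (feature id, sign)."""
        feature = point_index % self.n_features
        sign = np.where(point_index < self.n_features, 1.0, -1.0)
        return feature, sign

    @property
    def n_points(self) -> int:
        return 2 * self.n_features


def build_joint_index(P: ProjectedMatrix) -> MetricIndex:
    """Ball tree over the columns of [P | -P] (2n points, Euclidean metric)."""
    n = P.n_features
    if n == 0:
        raise ValueError("cannot index an empty feature set")
    points = np.vstack([P.values.T, -P.values.T])
    return MetricIndex(BallTree(points), n_features=n, feature_names=list(P.feature_names))


def resolve_k_prime(k: int, n: int, approximation_factor: float) -> int:
    """Per-query candidate count: ceil(a * k / n), at least 1, capped at 2n."""
    return min(2 * n, max(1, math.ceil(approximation_factor * k / n)))


def _batch_slices(n_queries: int, batch_size: Optional[int]) -> list[slice]:
    if batch_size is None:
        return [slice(0, n_queries)]
    return [slice(s, min(s + batch_size, n_queries)) for s in range(0, n_queries, batch_size)]


def _knn_batch(index: MetricIndex, queries: np.ndarray, query_ids: np.ndarray,
               k_prime: int, dualtree: bool) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    dist, idx = index.tree.query(queries, k=k_prime, dualtree=dualtree)
    feature, sign = index.origin(idx.ravel())
    qid = np.repeat(query_ids, k_prime)
    value = sign * (1.0 - dist.ravel() ** 2 / 2.0)
    keep = feature != qid  # drop self matches (+ at d=0, - at d=2)
    return qid[keep], feature[keep], np.clip(value[keep], -1.0, 1.0)


def _radius_batch(index: MetricIndex, queries: np.ndarray, query_ids: np.ndarray,
                  radius: float, signed_only: bool) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    idx_arr, dist_arr = index.tree.query_radius(queries, r=radius, return_distance=True)
    counts = np.fromiter((len(a) for a in idx_arr), dtype=np.int64, count=len(idx_arr))
    if counts.sum() == 0:
        empty = np.empty(0)
        return empty.astype(np.int64), empty.astype(np.int64), empty
    idx = np.concatenate(idx_arr)
    dist = np.concatenate(dist_arr)
    qid = np.repeat(query_ids, counts)
    feature, sign = index.origin(idx)
    value = sign * (1.0 - dist**2 / 2.0)
    keep = feature != qid
    if signed_only:
        keep &= sign > 0
    return qid[keep], feature[keep], np.clip(value[keep], -1.0, 1.0)


def _run_batches(index: MetricIndex, queries: np.ndarray, config: SearchConfig, worker):
    """Execute `worker` over query batches, optionally spilling results to disk."""
    slices = _batch_slices(queries.shape[0], config.batch_size)
    logger.info("running %d batch(es) with %d worker(s)", len(slices), config.n_workers)

    def run(sl: slice):
        return worker(index, queries[sl], np.arange(sl.start, sl.stop, dtype=np.int64))

    if config.low_memory:
        with tempfile.TemporaryDirectory(prefix="corrsearch_") as tmp:
            paths = []
            for b, sl in enumerate(slices):
                qid, feat, val = run(sl)
                path = os.path.join(tmp, f"batch{b}.npz")
                np.savez(path, i=qid, j=feat, value=val)
                paths.append(path)
            parts = [np.load(p) for p in paths]
            return [(p["i"], p["j"], p["value"]) for p in parts]
    if config.n_workers == 1 or len(slices) == 1:
        return [run(sl) for sl in slices]
    return Parallel(n_jobs=config.n_workers, backend="threading")(
        delayed(run)(sl) for sl in slices
    )


def _assemble(parts, feature_names: Sequence[str], ranking: str) -> EdgeList:
    i = np.concatenate([p[0] for p in parts]) if parts else np.empty(0, dtype=np.int64)
    j = np.concatenate([p[1] for p in parts]) if parts else np.empty(0, dtype=np.int64)
    v = np.concatenate([p[2] for p in parts]) if parts else np.empty(0)
    return canonical_edges(i, j, v, feature_names, ranking=ranking)


def topk_correlation_search(
    X: FeatureMatrix,
    k: int,
    config: Optional[SearchConfig] = None,
    method: str = "pearson",
) -> EdgeList:
    """Approximate global top-k correlated feature pairs via the joint index.

    With an approximation factor large enough that k' >= 2n the result is
    exact and identical to :func:`corrsearch.matrix.topk_from_matrix`.
    """
    config = config or SearchConfig()
    n = X.n_features
    total = count_pairs(n)
    if not 1 <= k <= total:
        raise ValueError(f"k must be in [1, {total}] for n={n} features, got {k}")
    P = project_correlation(X, method)
    index = build_joint_index(P)
    k_prime = resolve_k_prime(k, n, config.approximation_factor)
    logger.info(
        "top-k search: n=%d m=%d method=%s k=%d a=%g k'=%d",
        n, X.n_samples, method, k, config.approximation_factor, k_prime,
    )
    queries = P.values.T

    def worker(ix, q, qids):
        return _knn_batch(ix, q, qids, k_prime, config.dualtree)

    parts = _run_batches(index, queries, config, worker)
    edges = top_k_edges(_assemble(parts, X.feature_names, config.ranking), k)
    edges = recompute_values(edges, P.values)  # bit-identical to the matrix backend
    return symmetrize(edges) if config.symmetrize else edges


def threshold_correlation_search(
    X: FeatureMatrix,
    t: float,
    config: Optional[SearchConfig] = None,
    method: str = "pearson",
) -> EdgeList:
    """All pairs passing a correlation threshold, via exact radius queries.

    The threshold t is converted to the Euclidean radius sqrt(2 * (1 - t));
    no approximation factor is involved, the result is exact.
    """
    config = config or SearchConfig()
    if not 0.0 < t <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {t}")
    P = project_correlation(X, method)
    index = build_joint_index(P)
    radius = float(corr_to_distance(t))
    logger.info(
        "threshold search: n=%d m=%d method=%s t=%g radius=%g",
        X.n_features, X.n_samples, method, t, radius,
    )
    queries = P.values.T
    signed_only = config.ranking == "signed"

    def worker(ix, q, qids):
        return _radius_batch(ix, q, qids, radius, signed_only)

    parts = _run_batches(index, queries, config, worker)
    edges = _assemble(parts, X.feature_names, config.ranking)
    # radius queries use d <= r; keep the exact corr >= t contract under rounding
    key = np.abs(edges.value) if config.ranking == "abs" else edges.value
    keep = key >= t - 1e-12
    edges = EdgeList(
        edges.i[keep], edges.j[keep], edges.value[keep], edges.feature_names,
        ranking=config.ranking,
    )
    edges = recompute_values(edges, P.values)
    return symmetrize(edges) if config.symmetrize else edges


def merge_batch_results(
    partials: Iterable[EdgeList], k: int, ranking: str = "abs"
) -> EdgeList:
    """Merge per-batch edge collections into the global top-k.

    Concatenation -> canonicalization -> dedup -> partition to top-k -> sort;
    the output is independent of how queries were split into batches.  If
    fewer than k unique pairs were collected, all are returned and the
    ``truncated`` flag is set.
    """
    partials = list(partials)
    if not partials:
        raise ValueError("no partial results to merge")
    names = partials[0].feature_names
    parts = [(p.i, p.j, p.value) for p in partials]
    merged = _assemble(parts, names, ranking)
    out = top_k_edges(merged, k)
    if out.truncated:
        logger.warning("requested k=%d but only %d unique pairs found", k, len(out))
    return out


def empirical_sensitivity(
    X: FeatureMatrix,
    k: int,
    a_grid: Sequence[float],
    method: str = "pearson",
    ranking: str = "abs",
):
    """Measure top-k recall of the approximate search against the exact oracle.

    For each approximation factor a, sensitivity = |approx top-k ∩ exact
    top-k| / k.  Non-decreasing in a, and exactly 1.0 once k' >= 2n.
    Returns a list of (a, k_prime, sensitivity) tuples.
    """
    exact = topk_from_matrix(X, k, ranking=ranking, method=method).pair_set()
    rows = []
    for a in a_grid:
        config = SearchConfig(approximation_factor=a, ranking=ranking)
        approx = topk_correlation_search(X, k, config, method).pair_set()
        rows.append(
            (float(a), resolve_k_prime(k, X.n_features, a), len(approx & exact) / k)
        )
    return rows
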