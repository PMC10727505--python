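"""Single-cell coordination recipe.

Groups of cells (cell types) from two conditions are repeatedly resampled
with a dual bootstrap; in each replicate the strongest cell-cell correlations
(computed *between cells* over their functional markers) are tallied into
unordered group pairs; finally Cliff's delta of the per-pair tallies across
replicates screens for group pairs whose coordination changed between the two
conditions.  The default effect-size threshold of 0.622 corresponds to a
"very large" effect.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd

from .matrix import count_pairs
from .projections import FeatureMatrix
from .search import SearchConfig, topk_correlation_search
from .stats import cliffs_delta

__all__ = [
    "dual_bootstrap_sample",
    "count_topk_group_pairs",
    "effect_size_screen",
    "coordination_analysis",
    "VERY_LARGE_EFFECT",
]

logger = logging.getLogger(__name__)

VERY_LARGE_EFFECT = 0.622


def dual_bootstrap_sample(
    X: FeatureMatrix, labels: np.ndarray, target_per_group: int, seed: int
) -> tuple[FeatureMatrix, np.ndarray]:
    """Two-stage with-replacement resampling equalizing group sizes.

    Stage 1 draws n_g cells with replacement from group g (n_g = available
    count); stage 2 draws ``target_per_group`` cells with replacement from
    that intermediate sample.  Output has exactly target_per_group rows per
    group, in group order.
    """
    labels = np.asarray(labels)
    if len(labels) != X.n_samples:
        raise ValueError("labels length must match the number of rows")
    rng = np.random.default_rng(seed)
    rows, out_labels = [], []
    for group in pd.unique(labels):
        members = np.flatnonzero(labels == group)
        if len(members) == 0:
            raise ValueError(f"group {group!r} has no cells")
        stage1 = members[rng.integers(0, len(members), len(members))]
        stage2 = stage1[rng.integers(0, len(stage1), target_per_group)]
        rows.append(stage2)
        out_labels.append(np.full(target_per_group, group, dtype=object))
    rows = np.concatenate(rows)
    return (
        FeatureMatrix(X.values[rows], feature_names=list(X.feature_names)),
        np.concatenate(out_labels),
    )


def count_topk_group_pairs(
    cells: FeatureMatrix,
    labels: np.ndarray,
    k_fraction: float,
    method: str = "spearman",
    config: Optional[SearchConfig] = None,
) -> dict[tuple[str, str], int]:
    """Tally the strongest cell-cell correlations into unordered group pairs.

    Correlations are computed between cells over their marker values (the
    transposed orientation: cells act as features, markers as samples).
    ``k = round(k_fraction * n_cells * (n_cells - 1) / 2)``; the returned
    counts sum to k.
    """
    if not 0.0 < k_fraction <= 1.0:
        raise ValueError("k_fraction must be in (0, 1]")
    if cells.n_features < 3:
        raise ValueError("at least 3 markers are required")
    labels = np.asarray(labels)
    n_cells = cells.n_samples
    k = max(1, round(k_fraction * count_pairs(n_cells)))
    transposed = FeatureMatrix(
        cells.values.T, feature_names=[f"cell{i}" for i in range(n_cells)]
    )
    edges = topk_correlation_search(transposed, k, config, method)
    counts: dict[tuple[str, str], int] = {}
    for ci, cj in zip(edges.i, edges.j):
        pair = tuple(sorted((str(labels[ci]), str(labels[cj]))))
        counts[pair] = counts.get(pair, 0) + 1
    return counts


def _count_matrix(tables: list[dict[tuple[str, str], int]]) -> pd.DataFrame:
    pairs = sorted({p for t in tables for p in t})
    data = {p: [t.get(p, 0) for t in tables] for p in pairs}
    return pd.DataFrame(data)  # rows = replicates, columns = group pairs


def effect_size_screen(
    counts_condition1: list[dict[tuple[str, str], int]],
    counts_condition2: list[dict[tuple[str, str], int]],
    threshold: float = VERY_LARGE_EFFECT,
) -> pd.DataFrame:
    """Cliff's delta of per-pair top-k counts between conditions, screened.

    delta > 0 means condition 2 counts exceed condition 1 ("increase").
    Pairs with |delta| <= threshold are dropped.  Requires replicate-matched
    tables with at least 2 replicates each.
    """
    if min(len(counts_condition1), len(counts_condition2)) < 2:
        raise ValueError("at least 2 replicates per condition are required")
    if len(counts_condition1) != len(counts_condition2):
        raise ValueError("conditions must have the same number of replicates")
    m1 = _count_matrix(counts_condition1)
    m2 = _count_matrix(counts_condition2)
    pairs = sorted(set(m1.columns) | set(m2.columns))
    records = []
    for pair in pairs:
        c1 = m1[pair].to_numpy() if pair in m1 else np.zeros(len(counts_condition1))
        c2 = m2[pair].to_numpy() if pair in m2 else np.zeros(len(counts_condition2))
        delta = cliffs_delta(c2, c1)
        if abs(delta) > threshold:
            records.append(
                {
                    "group_a": pair[0],
                    "group_b": pair[1],
                    "delta": delta,
                    "direction": "increase" if delta > 0 else "decrease",
                }
            )
    return pd.DataFrame(records, columns=["group_a", "group_b", "delta", "direction"])


def coordination_analysis(
    X1: FeatureMatrix,
    labels1: np.ndarray,
    X2: FeatureMatrix,
    labels2: np.ndarray,
    target_per_group: int,
    k_fraction: float = 1e-4,
    n_replicates: int = 1000,
    threshold: float = VERY_LARGE_EFFECT,
    method: str = "spearman",
    config: Optional[SearchConfig] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Full recipe: dual bootstrap -> top-k pair counts -> Cliff's delta screen.

    Default k_fraction is the top 0.01% of all cell pairs and the default
    replicate count is 1,000 (reduce for desk-scale runs).
    """
    seeds = np.random.SeedSequence(seed).spawn(2 * n_replicates)
    tables1, tables2 = [], []
    for r in range(n_replicates):
        for X, labels, tables, ss in (
            (X1, labels1, tables1, seeds[2 * r]),
            (X2, labels2, tables2, seeds[2 * r + 1]),
        ):
            sample, sample_labels = dual_bootstrap_sample(
                X, labels, target_per_group, seed=int(ss.generate_state(1)[0])
            )
            tables.append(
                count_topk_group_pairs(sample, sample_labels, k_fraction, method, config)
            )
        if (r + 1) % 10 == 0:
            logger.info("coordination replicate %d/%d", r + 1, n_replicates)
    return effect_size_screen(tables1, tables2, threshold)
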