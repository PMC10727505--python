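"""Seeded generators with known ground truth for testing the search backends.

Block-correlated matrices use a latent-factor construction: each feature in a
block is a shared standard-normal signal plus independent noise with standard
deviation ``noise_sd``, so the expected within-block correlation is
``1 / (1 + noise_sd^2)``.  Two-condition matrices plant exact per-condition
sample correlations via Gram-Schmidt so differential ground truth is not
subject to sampling error.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np

from .edges import EdgeList, canonical_edges
from .projections import FeatureMatrix

__all__ = [
    "generate_block_correlated",
    "generate_two_condition",
    "generate_celllike",
]


def _block_assignments(n_features: int, block_sizes: Sequence[int]) -> list[np.ndarray]:
    if sum(block_sizes) > n_features:
        raise ValueError("block sizes exceed the number of features")
    out, start = [], 0
    for size in block_sizes:
        out.append(np.arange(start, start + size))
        start += size
    return out


def generate_block_correlated(
    n_features: int,
    m_samples: int,
    block_sizes: Sequence[int],
    rho: float,
    noise_sd: Optional[float] = None,
    seed: int = 0,
) -> tuple[FeatureMatrix, EdgeList]:
    """Matrix with blocks of correlated features among independent noise.

    Within a block every feature is z + noise_sd * eps with a shared latent z,
    giving expected correlation 1 / (1 + noise_sd^2).  When ``noise_sd`` is
    omitted it is derived from the target ``rho``; when both are given they
    must be consistent.  Returns the matrix and the ground-truth edge list of
    all within-block pairs (values = expected correlation).
    """
    if not 0.0 < rho <= 1.0:
        raise ValueError("rho must be in (0, 1]")
    implied_sd = math.sqrt((1.0 - rho) / rho)
    if noise_sd is None:
        noise_sd = implied_sd
    else:
        if noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if abs(1.0 / (1.0 + noise_sd**2) - rho) > 0.05:
            raise ValueError(
                f"noise_sd={noise_sd} implies within-block correlation "
                f"{1.0 / (1.0 + noise_sd ** 2):.3f}, inconsistent with rho={rho}"
            )
    rng = np.random.default_rng(seed)
    values = rng.standard_normal((m_samples, n_features))
    blocks = _block_assignments(n_features, block_sizes)
    gt_i, gt_j = [], []
    for block in blocks:
        latent = rng.standard_normal(m_samples)
        for f in block:
            values[:, f] = latent + noise_sd * rng.standard_normal(m_samples)
        for a in range(len(block)):
            for b in range(a + 1, len(block)):
                gt_i.append(block[a])
                gt_j.append(block[b])
    names = [f"f{i}" for i in range(n_features)]
    expected = np.full(len(gt_i), rho)
    truth = canonical_edges(np.asarray(gt_i, dtype=np.int64),
                            np.asarray(gt_j, dtype=np.int64), expected, names)
    return FeatureMatrix(values, feature_names=names), truth


def _planted_pair(rng: np.random.Generator, m: int, rho: float) -> tuple[np.ndarray, np.ndarray]:
    """Two length-m vectors whose *sample* Pearson correlation is exactly rho."""
    x = rng.standard_normal(m)
    e = rng.standard_normal(m)
    xc = x - x.mean()
    xs = xc / np.linalg.norm(xc)
    ec = e - e.mean()
    ec -= (ec @ xs) * xs  # orthogonalize against x in the centered space
    es = ec / np.linalg.norm(ec)
    y = rho * xs + math.sqrt(1.0 - rho * rho) * es
    return x, y


def generate_two_condition(
    n_features: int,
    m1: int,
    m2: int,
    planted_pairs: Sequence[tuple[int, int, float, float]],
    seed: int = 0,
) -> tuple[FeatureMatrix, FeatureMatrix, EdgeList]:
    """Two condition matrices with planted per-condition correlations.

    ``planted_pairs`` holds (i, j, rho1, rho2) records over disjoint feature
    pairs; the planted sample correlations are exact in each condition, so
    the ground-truth difference rho1 - rho2 is exact as well.  All remaining
    features are independent noise.
    """
    used: set[int] = set()
    for i, j, *_ in planted_pairs:
        if i in used or j in used or i == j:
            raise ValueError("planted pairs must be disjoint")
        used.update((i, j))
    if used and max(used) >= n_features:
        raise ValueError("planted pair index out of range")
    if min(m1, m2) < 3:
        raise ValueError("need at least 3 samples per condition")
    rng = np.random.default_rng(seed)
    X1 = rng.standard_normal((m1, n_features))
    X2 = rng.standard_normal((m2, n_features))
    gt_i, gt_j, gt_v = [], [], []
    for i, j, rho1, rho2 in planted_pairs:
        for X, m, rho in ((X1, m1, rho1), (X2, m2, rho2)):
            if not -1.0 <= rho <= 1.0:
                raise ValueError("planted correlations must be in [-1, 1]")
            x, y = _planted_pair(rng, m, rho)
            X[:, i] = x
            X[:, j] = y
        gt_i.append(i)
        gt_j.append(j)
        gt_v.append(rho1 - rho2)
    names = [f"f{i}" for i in range(n_features)]
    truth = canonical_edges(
        np.asarray(gt_i, dtype=np.int64), np.asarray(gt_j, dtype=np.int64),
        np.asarray(gt_v, dtype=np.float64), names,
    )
    return (
        FeatureMatrix(X1, feature_names=names),
        FeatureMatrix(X2, feature_names=names),
        truth,
    )


def generate_celllike(
    n_groups: int,
    cells_per_group: int,
    n_markers: int,
    group_effect: float = 1.0,
    seed: int = 0,
) -> tuple[FeatureMatrix, np.ndarray]:
    """Cell x marker matrix with grouped structure (cell types).

    Every group's cells share a marker-profile centroid (drawn with standard
    deviation ``group_effect``) plus unit-variance noise.  Returns the matrix
    (n_groups * cells_per_group rows, n_markers columns) and per-row group
    labels.  ``group_effect=0`` yields exchangeable cells across groups.
    """
    if min(n_groups, cells_per_group, n_markers) < 1:
        raise ValueError("all counts must be positive")
    rng = np.random.default_rng(seed)
    rows = n_groups * cells_per_group
    values = rng.standard_normal((rows, n_markers))
    labels = np.repeat([f"group{g}" for g in range(n_groups)], cells_per_group)
    centroids = group_effect * rng.standard_normal((n_groups, n_markers))
    values += np.repeat(centroids, cells_per_group, axis=0)
    names = [f"marker{i}" for i in range(n_markers)]
    cell_ids = [f"cell{i}" for i in range(rows)]
    return FeatureMatrix(values, feature_names=names, sample_ids=cell_ids), labels
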