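"""Feature-vector transforms reducing correlation computation to scalar products.

The central primitive is the *correlation projection*: mean-center each feature
column and scale it to unit Euclidean norm.  The scalar product of two
projected columns then equals their Pearson correlation, and the Euclidean
distance between them is a monotone transform of it, ``d = sqrt(2 * (1 - r))``.
A paired *differential* representation extends this so that a single scalar
product yields a correlation difference across two conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "FeatureMatrix",
    "ProjectedMatrix",
    "DifferentialRepresentation",
    "ConstantFeatureError",
    "project_correlation",
    "rank_transform",
    "project_differential",
    "corr_to_distance",
    "distance_to_corr",
    "diff_to_distance",
    "distance_to_diff",
    "METHODS",
]

METHODS = ("pearson", "spearman", "phi")

_RANGE_TOL = 1e-9


class ConstantFeatureError(ValueError):
    """Raised when a feature has zero variance and cannot be projected."""


def _as_names(names: Optional[Sequence[str]], n: int) -> list[str]:
    if names is None:
        return [f"f{i}" for i in range(n)]
    names = [str(x) for x in names]
    if len(names) != n:
        raise ValueError(f"expected {n} feature names, got {len(names)}")
    if len(set(names)) != len(names):
        seen: set[str] = set()
        dups = sorted({x for x in names if x in seen or seen.add(x)})
        raise ValueError(f"duplicate feature names: {dups[:5]}")
    return names


@dataclass
class FeatureMatrix:
    """A samples x features numeric matrix with named feature columns."""

    values: np.ndarray
    feature_names: list[str] = field(default=None)  # type: ignore[assignment]
    sample_ids: Optional[list[str]] = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 2:
            raise ValueError(f"expected a 2-D matrix, got shape {values.shape}")
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))
            r, c = bad[0]
            raise ValueError(
                f"non-finite value at sample {r}, feature column {c} "
                f"({len(bad)} non-finite entries total)"
            )
        self.values = values
        self.feature_names = _as_names(self.feature_names, values.shape[1])
        if self.sample_ids is not None:
            self.sample_ids = [str(s) for s in self.sample_ids]
            if len(self.sample_ids) != values.shape[0]:
                raise ValueError("sample_ids length does not match row count")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class ProjectedMatrix:
    """Correlation-projected feature columns: unit norm, zero mean."""

    values: np.ndarray
    method: str
    feature_names: list[str]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


@dataclass
class DifferentialRepresentation:
    """Paired delta/kappa columns whose scalar product is a correlation difference.

    ``delta`` stacks the projected columns of both conditions; ``kappa`` stacks
    the first condition's projection over the *negated* second.  Every column
    of either matrix has Euclidean norm sqrt(2).
    """

    delta: np.ndarray
    kappa: np.ndarray
    m1: int
    m2: int
    method: str
    feature_names: list[str]

    @property
    def n_features(self) -> int:
        return self.delta.shape[1]


def rank_transform(X: FeatureMatrix) -> FeatureMatrix:
    """Replace each column by its within-column ranks (ties get average rank)."""
    ranked = np.apply_along_axis(rankdata, 0, X.values) if X.values.size else X.values
    return FeatureMatrix(
        np.asarray(ranked, dtype=np.float64),
        feature_names=list(X.feature_names),
        sample_ids=X.sample_ids,
    )


def _check_binary(values: np.ndarray, names: Sequence[str]) -> None:
    for j in range(values.shape[1]):
        col = np.unique(values[:, j])
        if not np.isin(col, (0.0, 1.0)).all():
            raise ValueError(
                f"feature '{names[j]}' is not binary 0/1; the phi coefficient "
                f"requires pre-encoded 0/1 columns (found values {col[:4]})"
            )


def project_correlation(X: FeatureMatrix, method: str = "pearson") -> ProjectedMatrix:
    """Project feature columns so scalar products equal correlation coefficients.

    Parameters
    ----------
    X : FeatureMatrix
        Input matrix, samples as rows.
    method : {"pearson", "spearman", "phi"}
        Spearman ranks each column first; phi requires 0/1-encoded columns and
        reduces to Pearson on them.

    Raises
    ------
    ConstantFeatureError
        If any column is constant (zero centered norm).  Constant features
        should be removed beforehand, e.g. with
        :func:`corrsearch.io.preprocess_dataset`.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if X.n_samples < 2:
        raise ValueError("at least 2 samples are required for correlation")
    if method == "phi":
        _check_binary(X.values, X.feature_names)
    work = rank_transform(X) if method == "spearman" else X

    centered = work.values - work.values.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(centered, axis=0)
    zero = norms <= 0.0
    if zero.any():
        bad = [X.feature_names[j] for j in np.flatnonzero(zero)[:5]]
        raise ConstantFeatureError(
            f"constant feature(s) {bad} have zero variance; remove them with "
            "the preprocessing filter (preprocess_dataset) before projecting"
        )
    return ProjectedMatrix(centered / norms, method=method, feature_names=list(X.feature_names))


def project_differential(
    X1: FeatureMatrix, X2: FeatureMatrix, method: str = "pearson"
) -> DifferentialRepresentation:
    """Build the paired delta/kappa representation of two conditions.

    For any two features the scalar product ``<delta_x, kappa_y>`` equals
    ``cor(x1, y1) - cor(x2, y2)``, the difference of their correlations in the
    two conditions.
    """
    if X1.feature_names != X2.feature_names:
        raise ValueError("the two conditions must share identical feature names in order")
    P1 = project_correlation(X1, method)
    P2 = project_correlation(X2, method)
    delta = np.vstack([P1.values, P2.values])
    kappa = np.vstack([P1.values, -P2.values])
    return DifferentialRepresentation(
        delta=delta,
        kappa=kappa,
        m1=X1.n_samples,
        m2=X2.n_samples,
        method=method,
        feature_names=list(X1.feature_names),
    )


def corr_to_distance(c):
    """Map a correlation in [-1, 1] to the Euclidean distance of projections."""
    c = np.asarray(c, dtype=np.float64)
    if np.any(c < -1 - _RANGE_TOL) or np.any(c > 1 + _RANGE_TOL):
        raise ValueError("correlation outside [-1, 1]")
    return np.sqrt(np.maximum(2.0 * (1.0 - np.clip(c, -1.0, 1.0)), 0.0))


def distance_to_corr(d):
    """Inverse of :func:`corr_to_distance`: c = 1 - d^2 / 2 for d in [0, 2]."""
    d = np.asarray(d, dtype=np.float64)
    if np.any(d < -_RANGE_TOL) or np.any(d > 2 + _RANGE_TOL):
        raise ValueError("distance outside [0, 2]")
    return np.clip(1.0 - d * d / 2.0, -1.0, 1.0)


def diff_to_distance(g):
    """Map a correlation difference in [-2, 2] to differential-space distance."""
    g = np.asarray(g, dtype=np.float64)
    if np.any(g < -2 - _RANGE_TOL) or np.any(g > 2 + _RANGE_TOL):
        raise ValueError("correlation difference outside [-2, 2]")
    return np.sqrt(np.maximum(2.0 * (2.0 - np.clip(g, -2.0, 2.0)), 0.0))


def distance_to_diff(d):
    """Inverse of :func:`diff_to_distance`: g = 2 - d^2 / 2 for d in [0, 2*sqrt(2)]."""
    d = np.asarray(d, dtype=np.float64)
    hi = 2.0 * np.sqrt(2.0)
    if np.any(d < -_RANGE_TOL) or np.any(d > hi + _RANGE_TOL):
        raise ValueError("distance outside [0, 2*sqrt(2)]")
    return np.clip(2.0 - d * d / 2.0, -2.0, 2.0)
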