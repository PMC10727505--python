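"""Correlation-preserving coordinates for Euclidean-distance-based embedders.

The projected feature columns themselves serve as coordinates: the Euclidean
distance between the coordinates of two features equals sqrt(2 * (1 - r)), so
any off-the-shelf embedding method (t-SNE, UMAP, MDS, ...) applied to these
coordinates reflects the correlation structure without custom metrics.  Note
that negatively correlated features map to *large* distances by design.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .matrix import estimate_full_matrix_memory_gb, full_correlation_matrix
from .projections import FeatureMatrix, corr_to_distance, project_correlation

__all__ = ["correlation_embedding_coordinates", "correlation_distance_matrix"]


def correlation_embedding_coordinates(
    X: FeatureMatrix, method: str = "pearson"
) -> pd.DataFrame:
    """m-dimensional coordinates per feature (features as rows).

    Pairwise Euclidean distances between rows equal sqrt(2 * (1 - r)).
    """
    P = project_correlation(X, method)
    return pd.DataFrame(
        P.values.T,
        index=pd.Index(P.feature_names, name="feature"),
        columns=[f"dim{i}" for i in range(P.n_samples)],
    )


def correlation_distance_matrix(
    X: FeatureMatrix, method: str = "pearson", memory_cap_gb: float = 4.0
) -> pd.DataFrame:
    """Precomputed n x n distance matrix, entry (i, j) = sqrt(2 * (1 - r_ij)).

    Guarded by a memory estimate: refuses to materialize matrices whose
    float64 storage would exceed ``memory_cap_gb``.
    """
    est = estimate_full_matrix_memory_gb(X.n_features)
    if est > memory_cap_gb:
        raise MemoryError(
            f"distance matrix for n={X.n_features} features needs ~{est:.1f} GB, "
            f"exceeding the cap of {memory_cap_gb} GB; use embedding coordinates "
            "or the index-based search instead"
        )
    C = full_correlation_matrix(X, method)
    D = corr_to_distance(C.values)
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=C.feature_names, columns=C.feature_names)
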