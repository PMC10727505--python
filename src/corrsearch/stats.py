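"""Significance machinery for correlation edges.

Correlation p-values via the t-statistic, Bonferroni family-wise control, a
truncated Benjamini-Hochberg step-up procedure that adjusts only the k
smallest p-values without materializing the full distribution, and Cliff's
delta effect sizes.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

__all__ = [
    "correlation_pvalue",
    "bonferroni_adjust",
    "bh_truncated_adjust",
    "cliffs_delta",
    "attach_pvalues",
]


def correlation_pvalue(r, m: int):
    """Two-sided p-value of a correlation r observed on m samples.

    t = r * sqrt(m - 2) / sqrt(1 - r^2) with m - 2 degrees of freedom;
    |r| = 1 yields p = 0.
    """
    if m < 3:
        raise ValueError("at least 3 samples are required for a p-value")
    r = np.asarray(r, dtype=np.float64)
    if np.any(np.abs(r) > 1 + 1e-9):
        raise ValueError("correlation outside [-1, 1]")
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(m - 2) / np.sqrt(1.0 - r * r)
    p = np.where(np.abs(r) >= 1.0, 0.0, 2.0 * sps.t.sf(np.abs(t), df=m - 2))
    return p if p.ndim else float(p)


def bonferroni_adjust(p, n_features: int):
    """Multiply by the number of compared coefficients, (n^2 - n) / 2, cap at 1."""
    if n_features < 2:
        raise ValueError("n_features must be >= 2")
    p = np.asarray(p, dtype=np.float64)
    m = n_features * (n_features - 1) / 2.0
    out = np.minimum(1.0, p * m)
    return out if out.ndim else float(out)


def bh_truncated_adjust(p_topk, m_total: int, u_replacement: bool = False):
    """BH step-up adjustment of the k smallest of m_total p-values.

    Computes standard Benjamini-Hochberg adjusted values as if ranks
    k+1 .. m_total were padded with p = 1, without materializing them:
    ``P_adj(i) = min(min_{i <= j <= k} m_total * P_j / j, 1)``.  This is an
    upper bound on the full-distribution adjusted values and reduces to
    textbook BH when k = m_total.

    u_replacement : optionally apply an additional tightening to the values
        tied with the largest retained p-value, replacing their adjusted
        value by the bound ``u = m_total * P_k / (k + 1)`` when smaller.  Off
        by default; the published description of this micro-correction is
        ambiguous, so it is opt-in (see README).
    """
    p = np.asarray(p_topk, dtype=np.float64)
    if p.ndim != 1:
        raise ValueError("expected a 1-D vector of p-values")
    k = len(p)
    if k == 0:
        return p.copy()
    if k > m_total:
        raise ValueError("k cannot exceed the total number of tests")
    if np.any(np.diff(p) < 0):
        raise ValueError("p-values must be sorted ascending")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    ranks = np.arange(1, k + 1, dtype=np.float64)
    scaled = m_total * p / ranks
    adj = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    if u_replacement and k < m_total:
        u = m_total * p[-1] / (k + 1)
        if adj[-1] > u:
            adj = np.where(p == p[-1], min(u, 1.0), adj)
    return adj


def cliffs_delta(sample_a, sample_b) -> float:
    """Cliff's delta: (#{a > b} - #{a < b}) / (|A| * |B|) over all cross pairs."""
    a = np.asarray(sample_a, dtype=np.float64)
    b = np.asarray(sample_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    diff = a[:, None] - b[None, :]
    return float((np.count_nonzero(diff > 0) - np.count_nonzero(diff < 0)) / diff.size)


def attach_pvalues(edges, m: int, adjust: str | None = None,
                   m_total: int | None = None, u_replacement: bool = False):
    """Post-process an EdgeList with p-values and optional multiple-test adjustment.

    adjust : None, "bonferroni" (uses the feature count of the edge list) or
        "bh" (truncated BH over the edges present, with ``m_total`` tests in
        total; defaults to all feature pairs).
    """
    from .matrix import count_pairs

    p = np.atleast_1d(correlation_pvalue(edges.value, m))
    edges.p = p
    if adjust is None:
        return edges
    if adjust == "bonferroni":
        edges.p_adj = np.atleast_1d(bonferroni_adjust(p, len(edges.feature_names)))
    elif adjust == "bh":
        total = m_total if m_total is not None else count_pairs(len(edges.feature_names))
        order = np.argsort(p, kind="stable")
        adj_sorted = bh_truncated_adjust(p[order], total, u_replacement=u_replacement)
        p_adj = np.empty_like(p)
        p_adj[order] = adj_sorted
        edges.p_adj = p_adj
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return edges
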