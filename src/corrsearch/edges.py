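"""Edge lists: (feature_i, feature_j, value) records with deterministic ordering.

Canonical form: i < j, no self pairs, no duplicate pairs, sorted by the
ranking key descending with ties broken by ascending (i, j).  The ranking key
is ``|value|`` ("abs") or ``value`` ("signed").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EdgeList",
    "RANKINGS",
    "canonical_edges",
    "top_k_edges",
    "symmetrize",
    "recompute_values",
]

RANKINGS = ("abs", "signed")


def _key(values: np.ndarray, ranking: str) -> np.ndarray:
    if ranking not in RANKINGS:
        raise ValueError(f"unknown ranking {ranking!r}; expected one of {RANKINGS}")
    return np.abs(values) if ranking == "abs" else values


@dataclass
class EdgeList:
    """Pairs of feature indices with an associated value (correlation or difference)."""

    i: np.ndarray
    j: np.ndarray
    value: np.ndarray
    feature_names: list[str]
    p: Optional[np.ndarray] = None
    p_adj: Optional[np.ndarray] = None
    ranking: str = "abs"
    truncated: bool = False  # set when fewer pairs than requested k exist

    def __post_init__(self) -> None:
        self.i = np.asarray(self.i, dtype=np.int64)
        self.j = np.asarray(self.j, dtype=np.int64)
        self.value = np.asarray(self.value, dtype=np.float64)
        if not (len(self.i) == len(self.j) == len(self.value)):
            raise ValueError("i, j, value must have equal length")

    def __len__(self) -> int:
        return len(self.value)

    def pair_set(self) -> set[tuple[int, int]]:
        return set(zip(self.i.tolist(), self.j.tolist()))

    def to_dataframe(self) -> pd.DataFrame:
        names = np.asarray(self.feature_names, dtype=object)
        df = pd.DataFrame(
            {
                "feature_i": names[self.i],
                "feature_j": names[self.j],
                "value": self.value,
            }
        )
        if self.p is not None:
            df["p"] = self.p
        if self.p_adj is not None:
            df["p_adj"] = self.p_adj
        return df


def canonical_edges(
    i: np.ndarray,
    j: np.ndarray,
    value: np.ndarray,
    feature_names: Sequence[str],
    ranking: str = "abs",
) -> EdgeList:
    """Orient pairs to i < j, drop self pairs and duplicates, sort deterministically."""
    i = np.asarray(i, dtype=np.int64)
    j = np.asarray(j, dtype=np.int64)
    value = np.asarray(value, dtype=np.float64)

    keep = i != j
    i, j, value = i[keep], j[keep], value[keep]
    lo = np.minimum(i, j)
    hi = np.maximum(i, j)

    # dedup on the unordered pair; values agree by symmetry so keep-first is safe
    n = len(feature_names)
    code = lo * np.int64(n) + hi
    _, first = np.unique(code, return_index=True)
    first.sort()
    lo, hi, value = lo[first], hi[first], value[first]

    order = np.lexsort((hi, lo, -_key(value, ranking)))
    return EdgeList(lo[order], hi[order], value[order], list(feature_names), ranking=ranking)


def top_k_edges(edges: EdgeList, k: int) -> EdgeList:
    """Truncate a canonical edge list to its top-k prefix.

    If fewer than k unique pairs are available, all are returned and the
    ``truncated`` flag is set.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    truncated = len(edges) < k
    sl = slice(0, min(k, len(edges)))
    return EdgeList(
        edges.i[sl],
        edges.j[sl],
        edges.value[sl],
        edges.feature_names,
        p=None if edges.p is None else edges.p[sl],
        p_adj=None if edges.p_adj is None else edges.p_adj[sl],
        ranking=edges.ranking,
        truncated=truncated,
    )


def recompute_values(
    edges: EdgeList,
    left_columns: np.ndarray,
    right_columns: Optional[np.ndarray] = None,
    clip: float = 1.0,
) -> EdgeList:
    """Re-derive edge values as exact scalar products of the given columns.

    Both backends report values through this single code path so that their
    outputs are bit-identical: the matrix backend's BLAS product and the index
    backend's distance-derived values agree only to ~1 ulp otherwise.
    """
    right = left_columns if right_columns is None else right_columns
    if len(edges):
        vals = np.sum(left_columns[:, edges.i] * right[:, edges.j], axis=0)
        edges.value = np.clip(vals, -clip, clip)
    return edges


def symmetrize(edges: EdgeList) -> EdgeList:
    """Emit every (i, j, v) record also as (j, i, v); record count doubles."""
    i = np.concatenate([edges.i, edges.j])
    j = np.concatenate([edges.j, edges.i])
    value = np.concatenate([edges.value, edges.value])

    def _dup(a: Optional[np.ndarray]) -> Optional[np.ndarray]:
        return None if a is None else np.concatenate([a, a])

    order = np.lexsort((j, i, -_key(value, edges.ranking)))
    out = EdgeList(
        i[order],
        j[order],
        value[order],
        edges.feature_names,
        p=None if edges.p is None else _dup(edges.p)[order],
        p_adj=None if edges.p_adj is None else _dup(edges.p_adj)[order],
        ranking=edges.ranking,
        truncated=edges.truncated,
    )
    return out
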