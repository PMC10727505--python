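"""File formats and dataset preprocessing.

Dense matrices are CSV/TSV with a header row of feature names and one row per
sample; sparse matrices are MatrixMarket coordinate files with a plain-text
feature-name sidecar (one name per line).  Edge lists and coordinates are TSV.
All floats are written with 17 significant digits for lossless round trips.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .edges import EdgeList
from .projections import FeatureMatrix

__all__ = [
    "read_feature_matrix",
    "write_feature_matrix",
    "read_labels",
    "preprocess_dataset",
    "write_edge_list",
    "read_edge_list",
    "write_coordinates",
]

_FLOAT_FMT = "%.17g"


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".csv",):
        return "csv"
    if suffix in (".tsv", ".txt", ".tab"):
        return "tsv"
    if suffix in (".mtx", ".mm"):
        return "mtx"
    raise ValueError(f"cannot infer format from extension {suffix!r}; pass format=")


def _check_unique_header(names: Sequence[str]) -> None:
    seen: set[str] = set()
    dups = [x for x in names if x in seen or seen.add(x)]
    if dups:
        raise ValueError(f"duplicate feature names in header: {sorted(set(dups))[:5]}")


def read_feature_matrix(
    path: str | Path,
    format: Optional[str] = None,
    names_path: str | Path | None = None,
    transpose: bool = False,
) -> FeatureMatrix:
    """Load a samples x features matrix from CSV/TSV or MatrixMarket MTX.

    MTX input is densified and requires a feature-name sidecar (default:
    ``<path>.names``, one name per line).  ``transpose`` reads a
    features-as-rows file: the first column holds feature names and the
    header row holds sample ids.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        if transpose:
            df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
            names = [str(x) for x in df.index]
            _check_unique_header(names)
            values = df.to_numpy(dtype=np.float64).T
        else:
            with open(path, newline="") as fh:
                header = next(csv.reader(fh, delimiter=sep))
            _check_unique_header(header)
            df = pd.read_csv(path, sep=sep, float_precision="round_trip")
            values = df.to_numpy(dtype=np.float64)
            names = list(df.columns)
    elif fmt == "mtx":
        mat = spio.mmread(path)
        values = mat.toarray() if sparse.issparse(mat) else np.asarray(mat)
        values = values.astype(np.float64)
        sidecar = Path(names_path) if names_path else Path(str(path) + ".names")
        names = [line.strip() for line in sidecar.read_text().splitlines() if line.strip()]
        if transpose:
            values = values.T
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if len(names) != values.shape[1]:
        raise ValueError(
            f"{len(names)} feature names for {values.shape[1]} columns in {path.name}"
        )
    bad = np.argwhere(~np.isfinite(values))
    if len(bad):
        r, c = bad[0]
        raise ValueError(
            f"non-finite value in {path.name} at sample row {r}, feature '{names[c]}'"
        )
    return FeatureMatrix(values, feature_names=names)


def write_feature_matrix(X: FeatureMatrix, path: str | Path, format: Optional[str] = None) -> None:
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt not in ("csv", "tsv"):
        raise ValueError("only csv/tsv output is supported")
    sep = "," if fmt == "csv" else "\t"
    pd.DataFrame(X.values, columns=X.feature_names).to_csv(
        path, sep=sep, index=False, float_format=_FLOAT_FMT
    )


def read_labels(path: str | Path) -> np.ndarray:
    """One label per line (matching matrix rows), or a single-column file."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    return np.asarray(lines, dtype=object)


def preprocess_dataset(X: FeatureMatrix) -> tuple[FeatureMatrix, list[dict]]:
    """Standard dataset cleaning: clamp, drop constants, drop duplicates.

    Order matters and is fixed: (1) negative values are set to 0, (2)
    features left with a single unique value are removed, (3) exact duplicate
    features are removed keeping the first occurrence.  Returns the cleaned
    matrix and a removal report (feature name + reason per removal).
    """
    values = np.where(X.values < 0, 0.0, X.values)
    report: list[dict] = []
    keep: list[int] = []
    for j in range(values.shape[1]):
        col = values[:, j]
        if np.all(col == col[0]):
            report.append({"feature": X.feature_names[j], "reason": "constant"})
        else:
            keep.append(j)

    kept: list[int] = []
    seen: dict[bytes, str] = {}
    for j in keep:
        fingerprint = values[:, j].tobytes()
        if fingerprint in seen:
            report.append(
                {"feature": X.feature_names[j], "reason": f"duplicate_of:{seen[fingerprint]}"}
            )
        else:
            seen[fingerprint] = X.feature_names[j]
            kept.append(j)
    if not kept:
        raise ValueError("preprocessing removed all features")
    out = FeatureMatrix(
        values[:, kept],
        feature_names=[X.feature_names[j] for j in kept],
        sample_ids=X.sample_ids,
    )
    return out, report


def write_edge_list(edges: EdgeList, path: str | Path) -> None:
    """TSV with columns feature_i, feature_j, value[, p, p_adj]; lossless floats."""
    edges.to_dataframe().to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_edge_list(path: str | Path, feature_names: Sequence[str]) -> EdgeList:
    df = pd.read_csv(path, sep="\t", dtype={"feature_i": str, "feature_j": str},
                     float_precision="round_trip")
    lookup = {name: idx for idx, name in enumerate(feature_names)}
    i = np.asarray([lookup[x] for x in df["feature_i"]], dtype=np.int64)
    j = np.asarray([lookup[x] for x in df["feature_j"]], dtype=np.int64)
    return EdgeList(
        i,
        j,
        df["value"].to_numpy(dtype=np.float64),
        list(feature_names),
        p=df["p"].to_numpy() if "p" in df else None,
        p_adj=df["p_adj"].to_numpy() if "p_adj" in df else None,
    )


def write_coordinates(coords: pd.DataFrame, path: str | Path) -> None:
    coords.to_csv(path, sep="\t", float_format=_FLOAT_FMT)
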