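"""Readers and writers for feature tables, LIBSVM sparse files and kernel TSVs.

Kernel matrices travel as TSV with a header row of sample identifiers and
identical row labels; floats are written with 17 significant digits so a
write/read round trip is bit-exact.  Label columns accept {+1,-1}, {0,1} or
{1,2} and are mapped to {-1,+1}.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.datasets import dump_svmlight_file, load_svmlight_file

from .kernels import FeatureMatrix
from .spectral import KernelMatrix

__all__ = [
    "read_feature_table",
    "read_libsvm_file",
    "write_libsvm_file",
    "read_kernel_matrix",
    "write_kernel_matrix",
    "read_labels",
]

logger = logging.getLogger("projkernel")

_FLOAT_FMT = "%.17g"


def _delimiter(path: str) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def _map_labels(raw: np.ndarray, source: str) -> np.ndarray:
    values = np.unique(raw)
    if values.size != 2:
        raise ValueError(f"{source}: expected exactly 2 label values, got {values!r}")
    allowed = [{-1, 1}, {0, 1}, {1, 2}]
    vset = set(np.asarray(values, dtype=float).tolist())
    if vset not in allowed:
        raise ValueError(f"{source}: label values {sorted(vset)} not in {{+1,-1}}, {{0,1}} or {{1,2}}")
    y = np.where(raw == values.max(), 1, -1).astype(int)
    if vset != {-1, 1}:
        logger.info("%s: labels %s mapped to {-1,+1}", source, sorted(vset))
    return y


def read_feature_table(path, label_column: str | None = None):
    """Read a CSV/TSV sample-by-attribute table (delimiter from extension).

    Returns a FeatureMatrix, or ``(FeatureMatrix, labels)`` when
    ``label_column`` names a binary label column.
    """
    df = pd.read_csv(path, sep=_delimiter(path), index_col=0, float_precision="round_trip")
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"{path}: duplicate sample identifiers {dupes}")
    labels = None
    if label_column is not None:
        if label_column not in df.columns:
            raise ValueError(f"{path}: no label column {label_column!r}")
        labels = _map_labels(df[label_column].to_numpy(), str(path))
        df = df.drop(columns=[label_column])
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric feature cells ({exc})") from exc
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{path}: non-finite feature cells")
    fm = FeatureMatrix(values, sample_ids=tuple(map(str, df.index)),
                       attribute_ids=tuple(map(str, df.columns)))
    return fm if labels is None else (fm, labels)


def read_libsvm_file(path):
    """Read LIBSVM sparse text (1-based indices on disk, dense 0-based in memory)."""
    try:
        X, y = load_svmlight_file(str(path), zero_based=False)
    except ValueError as exc:
        raise ValueError(f"{path}: malformed LIBSVM file ({exc})") from exc
    logger.info("%s: LIBSVM 1-based indices shifted to 0-based", path)
    return FeatureMatrix(np.asarray(X.todense())), _map_labels(y, str(path))


def write_libsvm_file(X: FeatureMatrix, labels, path) -> None:
    dump_svmlight_file(X.values, np.asarray(labels), str(path), zero_based=False)


def read_kernel_matrix(path, tol_rel: float = 1e-10) -> KernelMatrix:
    """Read a kernel TSV; validates squareness, matching row/column ids and
    symmetry (relative tolerance ``tol_rel``)."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: kernel table is {df.shape[0]}x{df.shape[1]}, not square")
    if list(map(str, df.index)) != list(map(str, df.columns)):
        raise ValueError(f"{path}: row labels do not match column header")
    values = df.to_numpy(dtype=float)
    asym = float(np.max(np.abs(values - values.T))) if values.size else 0.0
    scale = max(float(np.max(np.abs(values))) if values.size else 0.0, 1.0)
    if asym > tol_rel * scale:
        raise ValueError(f"{path}: asymmetric kernel (max |K-K'| = {asym:.3e})")
    return KernelMatrix(values, symmetrize=True)


def write_kernel_matrix(K: KernelMatrix, path, sample_ids=None) -> None:
    ids = list(sample_ids) if sample_ids is not None else [f"s{i}" for i in range(K.n)]
    df = pd.DataFrame(K.values, index=ids, columns=ids)
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_labels(path) -> np.ndarray:
    """Read a one-column label file (optionally with header/ids) to {-1,+1}."""
    df = pd.read_csv(path, sep=_delimiter(path), header=None)
    col = df.iloc[:, -1]
    if not pd.api.types.is_numeric_dtype(col):  # header row present
        df = pd.read_csv(path, sep=_delimiter(path))
        col = df.iloc[:, -1]
    return _map_labels(col.to_numpy(), str(path))
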