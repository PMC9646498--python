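"""Readers and writers for expression tables, MTX triplets and result tables.

All tabular output is TSV with a header row; floats are written at fixed
precision (6 decimals) so a write → read round trip is lossless at that
precision. Gene ids are opaque strings — no symbol/identifier mapping.
"""

from __future__ import annotations

import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .data import (
    DataValidationError,
    ExpressionMatrix,
    make_expression_matrix,
    validate_cell_table,
    validate_purity_ploidy,
)

log = logging.getLogger("tms")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[tms %(levelname)s] %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)

FLOAT_FORMAT = "%.6f"


class ParseError(DataValidationError):
    """Malformed input file (bad header, negative value, duplicate id...)."""


def read_expression(path, fmt: str | None = None, role: str = "mixed",
                    features_path=None, barcodes_path=None) -> ExpressionMatrix:
    """Read a genes × samples expression table.

    ``fmt`` is one of ``tsv``, ``csv`` or ``mtx``; inferred from the file
    suffix when omitted. MTX input needs accompanying ``features_path`` and
    ``barcodes_path`` line lists (gene ids and cell/sample ids).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt == "mtx":
        return _read_mtx(path, features_path, barcodes_path, role)
    if fmt not in ("tsv", "csv"):
        raise ParseError(f"unsupported expression format: {fmt!r}")
    sep = "\t" if fmt == "tsv" else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[1] == 0:
        raise ParseError(f"{path}: no sample columns found")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index
            raise ParseError(
                f"{path}: non-numeric value in column {col!r}, row {bad[0]!r}"
            )
    arr = df.to_numpy(dtype=float)
    if (arr < 0).any():
        g, s = np.argwhere(arr < 0)[0]
        raise ParseError(
            f"{path}: negative count at gene {df.index[g]!r}, sample {df.columns[s]!r}"
        )
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate gene id {dup!r}")
    return make_expression_matrix(df.astype(float), role=role)


def _read_mtx(path, features_path, barcodes_path, role) -> ExpressionMatrix:
    if features_path is None or barcodes_path is None:
        raise ParseError("MTX input requires features and barcodes files")
    mat = scipy.io.mmread(str(path))
    genes = [ln.split("\t")[0] for ln in Path(features_path).read_text().splitlines() if ln]
    cells = [ln.strip() for ln in Path(barcodes_path).read_text().splitlines() if ln]
    dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
    if dense.shape != (len(genes), len(cells)):
        raise ParseError(
            f"{path}: matrix shape {dense.shape} does not match "
            f"{len(genes)} features × {len(cells)} barcodes"
        )
    df = pd.DataFrame(dense, index=genes, columns=cells)
    return make_expression_matrix(df, role=role)


def read_purity_ploidy(path) -> pd.DataFrame:
    """Read a TSV with columns sample_id, purity, ploidy, caller."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return validate_purity_ploidy(df)


def read_cell_table(path) -> pd.DataFrame:
    """Read a per-cell TSV with cell_id, sample_id, cell_class, total_umi, gene_count."""
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "sample_id": str})
    return validate_cell_table(df)


def write_table(rows: pd.DataFrame, path) -> None:
    """Write a result table as TSV at fixed float precision (6 decimals)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_expression(mat: ExpressionMatrix, path) -> None:
    """Write an expression matrix as TSV (gene id index, sample columns)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    mat.values.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# Scale normalization
# ---------------------------------------------------------------------------

def _sample_statistic(values: pd.DataFrame, scheme: str) -> np.ndarray:
    arr = values.to_numpy(dtype=float)
    if scheme == "upper-quartile":
        stats = np.empty(arr.shape[1])
        for j in range(arr.shape[1]):
            nz = arr[arr[:, j] > 0, j]
            stats[j] = np.quantile(nz, 0.75) if nz.size else 0.0
        return stats
    if scheme == "median-of-totals":
        return arr.sum(axis=0)
    raise DataValidationError(f"unknown normalization scheme: {scheme!r}")


def lower_median(x: np.ndarray) -> float:
    """Median taking the lower of the two central order statistics.

    The reference value of scale normalization is then always a statistic an
    actual sample attained, which keeps the per-sample factors interpretable.
    """
    xs = np.sort(np.asarray(x, dtype=float))
    return float(xs[(len(xs) - 1) // 2])


def scale_normalize(mat: ExpressionMatrix, scheme: str = "upper-quartile"):
    """Rescale every sample so its scheme statistic equals the cohort reference.

    Schemes: ``upper-quartile`` (0.75 quantile of each sample's non-zero
    counts) or ``median-of-totals`` (per-sample column total). The reference is
    the lower median of the per-sample statistics. Returns the normalized
    matrix; the applied per-sample factors are logged at DEBUG level and
    returned on the matrix under ``scale_factors``.
    """
    arr = mat.values.to_numpy(dtype=float)
    totals = arr.sum(axis=0)
    if (totals == 0).any():
        j = int(np.argwhere(totals == 0)[0, 0])
        raise DataValidationError(f"sample {mat.sample_ids[j]!r} has all-zero counts")
    stats = _sample_statistic(mat.values, scheme)
    ref = lower_median(stats)
    factors = ref / stats
    out = mat.with_values(mat.values * factors, normalized=True)
    out.scale_factors = pd.Series(factors, index=mat.sample_ids)
    log.debug("scale_normalize(%s): factors %s", scheme, np.round(factors, 4).tolist())
    return out
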