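"""Delimited-text readers and writers for panel matrices and results.

TSV is the default dialect (CSV accepted by file extension).  Cp and ΔCp
matrices are written rows = miRNAs, columns = samples, with undetected
cells as the empty field; readers also accept ``NA``.  Lines starting
with ``#`` are treated as a comment preamble, so instrument-export
headers can be left in place.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    CYCLE_MAX,
    AssayQC,
    CpMatrix,
    DataError,
    NormalizedMatrix,
    validate_metadata,
)

NA_VALUES = ["", "NA"]


def _sep(path: Path) -> str:
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


def _read_table(path, index_col=0) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    try:
        df = pd.read_csv(
            path,
            sep=_sep(path),
            index_col=index_col,
            comment="#",
            na_values=NA_VALUES,
            keep_default_na=False,
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise DataError(f"cannot parse {path}: {exc}") from exc
    return df


def _check_duplicate_rows(df: pd.DataFrame, path) -> None:
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()]
        first = dup[0]
        # +2: header line plus 1-based numbering of the first data row
        line = int(np.flatnonzero(df.index == first)[1]) + 2
        raise DataError(f"duplicate miRNA id {first!r} in {path} (line {line})")


def read_cp_matrix(path, plates: pd.Series | None = None, calibrator_ids=()) -> CpMatrix:
    """Read a Cp matrix (first column miRNA ids, header row sample ids).

    Empty and ``NA`` cells become undetected.  Values outside
    ``(0, 40]``, duplicate ids and malformed numerics are parse errors.
    If ``plates`` is omitted, all samples are placed on a single plate.
    """
    df = _read_table(path)
    _check_duplicate_rows(df, path)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise DataError(f"non-numeric Cp value in {path}: {exc}") from exc
    arr = df.to_numpy()
    bad = ~np.isnan(arr) & ~((arr > 0) & (arr <= CYCLE_MAX))
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise DataError(
            f"Cp value {arr[i, j]!r} at ({df.index[i]}, {df.columns[j]}) in {path} "
            f"outside (0, {CYCLE_MAX}] (line {i + 2})"
        )
    if plates is None:
        plates = pd.Series("plate-1", index=df.columns)
    return CpMatrix(df, plates, tuple(calibrator_ids))


def write_cp_matrix(matrix: CpMatrix, path) -> None:
    matrix.values.rename_axis("mirna_id").to_csv(path, sep=_sep(Path(path)), na_rep="NA")


def read_normalized_matrix(path, plates: pd.Series | None = None) -> NormalizedMatrix:
    """Read a ΔCp matrix written by :func:`write_normalized_matrix`."""
    df = _read_table(path)
    _check_duplicate_rows(df, path)
    df = df.astype(float)
    if plates is None:
        plates = pd.Series("plate-1", index=df.columns)
    return NormalizedMatrix(
        values=df,
        plates=plates,
        sample_global_mean=pd.Series(np.nan, index=df.columns),
    )


def write_normalized_matrix(norm: NormalizedMatrix, path) -> None:
    norm.values.rename_axis("mirna_id").to_csv(path, sep=_sep(Path(path)), na_rep="NA")


def read_metadata(path) -> pd.DataFrame:
    """Read and validate a sample metadata table (index = sample id)."""
    return validate_metadata(_read_table(path))


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.rename_axis("sample_id").to_csv(path, sep=_sep(Path(path)))


def read_assay_qc(melt_path, neg_control_path) -> AssayQC:
    """Read melt-peak counts (matrix) and per-plate negative controls."""
    melt = _read_table(melt_path)
    neg = _read_table(neg_control_path)
    if neg.shape[1] != 1:
        raise DataError(
            f"{neg_control_path}: expected two columns (plate, negative_control_cp)"
        )
    return AssayQC(melt_peaks=melt, negative_control_cp=neg.iloc[:, 0].astype(float))


def write_assay_qc(qc: AssayQC, melt_path, neg_control_path) -> None:
    qc.melt_peaks.rename_axis("mirna_id").to_csv(melt_path, sep=_sep(Path(melt_path)))
    qc.negative_control_cp.rename("negative_control_cp").rename_axis("plate").to_csv(
        neg_control_path, sep=_sep(Path(neg_control_path)), na_rep="NA"
    )


def write_table(df: pd.DataFrame, path) -> None:
    """Write any result table (index kept) as delimited text."""
    df.to_csv(path, sep=_sep(Path(path)), na_rep="NA")


def read_truth_table(path) -> pd.DataFrame:
    return _read_table(path, index_col=None)


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
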