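"""Reading and writing count matrices, metadata and result tables.

File conventions
----------------
Count matrix: delimited text, header row = sample ids, first column =
barcode ids, cells = nonnegative numbers. Metadata: first column = sample
id, remaining columns = variables. Comma- and tab-delimited files are both
accepted; the delimiter is sniffed from the header line unless given
explicitly. Decimal separator is always "." (locale-independent).
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    CountMatrix,
    MetadataTable,
    ValidationReport,
    ValueKind,
)

__all__ = [
    "read_count_matrix",
    "read_metadata",
    "validate_dataset",
    "write_table",
    "sniff_delimiter",
]


def sniff_delimiter(path: str | os.PathLike) -> str:
    """Return "\\t" if the header line contains a tab, else ",". """
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_count_matrix(
    path: str | os.PathLike,
    delimiter: str | None = None,
    value_kind: ValueKind | str = ValueKind.RAW_READS,
) -> CountMatrix:
    """Read a barcode x sample count matrix from delimited text.

    Raises ``ValueError`` naming the offending identifier or cell for
    duplicated barcode ids, negative or non-numeric values, and empty
    matrices. All-zero rows are retained (readers never silently drop
    barcodes; analyses that need nonzero rows drop them with a warning).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = delimiter or sniff_delimiter(path)
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise ValueError(f"empty count matrix in {path}")
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise ValueError(f"duplicate barcode identifier {dup}")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().to_numpy()
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"non-numeric value {raw.iat[r, c]!r} at ({raw.index[r]}, {raw.columns[c]})"
        )
    neg = (numeric.to_numpy() < 0)
    if neg.any():
        r, c = np.argwhere(neg)[0]
        raise ValueError(f"negative count at ({raw.index[r]}, {raw.columns[c]})")
    numeric.index = numeric.index.astype(str)
    numeric.columns = numeric.columns.astype(str)
    numeric.index.name = "barcode"
    return CountMatrix(numeric, ValueKind(value_kind))


def read_metadata(
    path: str | os.PathLike, delimiter: str | None = None
) -> MetadataTable:
    """Read the per-sample metadata table (first column = sample id)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = delimiter or sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    if df.shape[1] == 0:
        raise ValueError(f"metadata in {path} has no variable columns")
    df.index = df.index.astype(str)
    df.index.name = "sample"
    return MetadataTable(df)


def validate_dataset(cm: CountMatrix, md: MetadataTable) -> ValidationReport:
    """Cross-check a count matrix against its metadata.

    Samples present on one side only are errors; all-zero barcodes and
    all-zero samples are warnings. Pure: neither input is mutated.
    """
    report = ValidationReport()
    cm_samples = set(cm.sample_ids)
    md_samples = set(md.sample_ids)
    for s in cm.sample_ids:
        if s not in md_samples:
            report.add("error", s, "sample in count matrix but not in metadata")
    for s in md.sample_ids:
        if s not in cm_samples:
            report.add("error", s, "sample in metadata but not in count matrix")
    vals = cm.data.to_numpy()
    for i in np.flatnonzero(vals.sum(axis=1) == 0):
        report.add("warning", cm.barcode_ids[i], "barcode has zero counts in every sample")
    for j in np.flatnonzero(vals.sum(axis=0) == 0):
        report.add("warning", cm.sample_ids[j], "sample has zero counts for every barcode")
    return report


def write_table(
    obj: CountMatrix | MetadataTable | pd.DataFrame,
    path: str | os.PathLike,
    delimiter: str | None = None,
) -> None:
    """Write a result table as delimited text.

    Delimiter defaults to the file suffix convention (``.tsv`` -> tab,
    else comma). Integer-valued count matrices round-trip exactly; floats
    are written with 17 significant digits so re-reading reproduces them.
    """
    path = Path(path)
    sep = delimiter or ("\t" if path.suffix.lower() == ".tsv" else ",")
    if isinstance(obj, CountMatrix):
        df = obj.data
        vals = df.to_numpy()
        if np.issubdtype(vals.dtype, np.integer) or (
            np.isfinite(vals).all() and (vals == np.round(vals)).all()
        ):
            df = df.astype(np.int64)
        df.to_csv(path, sep=sep, float_format="%.17g")
    elif isinstance(obj, MetadataTable):
        obj.data.to_csv(path, sep=sep)
    elif isinstance(obj, pd.DataFrame):
        obj.to_csv(path, sep=sep, float_format="%.17g")
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
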