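"""Adapter for single-cell lineage-tracing data.

Converts a per-cell table (cell id, barcode, cell-type annotation, plus
optional extras such as the starting population or timepoint) into a
barcodes x cell-types matrix of cell counts — the same substrate every
other analysis consumes. The tally is deliberately raw: no normalization
or extra QC is applied at this stage.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .datamodel import CountMatrix, ValidationReport, ValueKind
from .io import sniff_delimiter

__all__ = ["CellTable", "read_cell_table", "tally_barcodes_by_celltype"]


@dataclass
class CellTable:
    """Per-cell annotations: one row per (cell, barcode) call.

    A cell with several barcode calls occupies several rows (strict
    single-barcode handling is the tally's job). Cell ids must be unique
    per barcode call.
    """

    data: pd.DataFrame
    barcode_col: str = "barcode"
    type_col: str = "cell_type"
    cell_col: str = "cell_id"

    def __post_init__(self) -> None:
        for col in (self.cell_col, self.barcode_col, self.type_col):
            if col not in self.data.columns:
                raise ValueError(f"cell table lacks column {col!r}")
        if self.data.duplicated([self.cell_col, self.barcode_col]).any():
            raise ValueError("duplicated (cell, barcode) rows in cell table")


def read_cell_table(
    path: str | os.PathLike,
    barcode_col: str = "barcode",
    type_col: str = "cell_type",
    cell_col: str = "cell_id",
    delimiter: str | None = None,
) -> CellTable:
    path = Path(path)
    sep = delimiter or sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    return CellTable(df, barcode_col=barcode_col, type_col=type_col, cell_col=cell_col)


def tally_barcodes_by_celltype(
    cells: CellTable,
    group_extra: list[str] | None = None,
    single_barcode_only: bool = False,
) -> tuple[CountMatrix, ValidationReport]:
    """Count cells per barcode per cell type (x optional extra groups).

    Cells without a barcode or without a cell-type annotation are dropped
    and counted in the report. ``single_barcode_only`` additionally drops
    every cell with more than one barcode call (by default each (cell,
    barcode) pair contributes one count). Column labels are the cell type,
    underscore-joined with the extra group values when given.
    """
    df = cells.data
    if df.empty:
        raise ValueError("empty cell table")
    report = ValidationReport()
    keep = (df[cells.barcode_col].astype(str).str.strip() != "") & (
        df[cells.type_col].astype(str).str.strip() != ""
    )
    dropped = int((~keep).sum())
    if dropped:
        report.add("warning", "", f"dropped {dropped} cell(s) without barcode or cell type")
    df = df.loc[keep]
    if single_barcode_only:
        n_bc = df.groupby(cells.cell_col)[cells.barcode_col].transform("nunique")
        multi = int((n_bc > 1).sum())
        if multi:
            report.add("warning", "", f"dropped {multi} row(s) from multi-barcode cells")
        df = df.loc[n_bc == 1]
    if df.empty:
        raise ValueError("no cells left after filtering")
    group_cols = [cells.type_col] + list(group_extra or [])
    for col in group_cols:
        if col not in df.columns:
            raise ValueError(f"cell table lacks column {col!r}")
    key = df[group_cols].astype(str).agg("_".join, axis=1)
    tally = pd.crosstab(df[cells.barcode_col], key)
    tally.index.name = "barcode"
    tally.columns.name = None
    return CountMatrix(tally.astype(float), ValueKind.CELL_COUNTS), report
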