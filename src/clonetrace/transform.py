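"""Normalization and transformation stack.

Every analysis downstream of raw counts starts from within-sample
proportions (column normalization); visualizations add a variance-
stabilizing arcsine-square-root or log scale, and the lineage-bias
classifier adds a row normalization that turns each barcode's abundances
across cell types into the row-stochastic proportions P_bc.
"""

from __future__ import annotations

import warnings

import numpy as np

from .datamodel import CountMatrix, ValueKind

__all__ = [
    "normalize_columns",
    "scale_columns",
    "arcsin_sqrt",
    "log_transform",
    "row_normalize",
]


def normalize_columns(cm: CountMatrix) -> CountMatrix:
    """Divide each column by its total: reads -> within-sample proportions.

    All-zero columns are left unchanged with a warning. Idempotent.
    """
    df = cm.data.astype(float)
    sums = df.sum(axis=0)
    zero = sums[sums == 0].index.tolist()
    if zero:
        warnings.warn(f"all-zero sample(s) left unnormalized: {zero}")
    out = df.div(sums.where(sums > 0, 1.0), axis=1)
    return CountMatrix(out, ValueKind.NORMALIZED)


def scale_columns(cm: CountMatrix, factor: float) -> CountMatrix:
    """Multiply normalized proportions by a fixed factor (e.g. 1e5)."""
    if factor <= 0:
        raise ValueError("scale factor must be positive")
    if cm.value_kind is not ValueKind.NORMALIZED:
        raise ValueError("scale_columns expects a column-normalized matrix")
    return CountMatrix(cm.data * factor, ValueKind.SCALED, scale_factor=factor)


def arcsin_sqrt(cm: CountMatrix, clip_tol: float = 1e-9) -> CountMatrix:
    """Arcsine-square-root variance-stabilizing transform, asin(sqrt(p)).

    Defined on proportions only: 0 -> 0, 0.5 -> pi/4, 1 -> pi/2. Values in
    (1, 1+clip_tol] are clipped to 1; anything larger means the matrix was
    not normalized first and is an error.
    """
    vals = cm.data.to_numpy(dtype=float)
    if (vals > 1.0 + clip_tol).any():
        raise ValueError("arcsin requires proportions; normalize first")
    out = np.arcsin(np.sqrt(np.clip(vals, 0.0, 1.0)))
    df = cm.data.copy()
    df[:] = out
    return CountMatrix(df, ValueKind.TRANSFORMED)


def log_transform(cm: CountMatrix, pseudocount: float = 1.0) -> CountMatrix:
    """Shifted log10: x -> log10(x + pseudocount) - log10(pseudocount).

    Anchored so zero maps to zero for any pseudocount; strictly monotone.
    For proportion-scale data a pseudocount of 1/total (one read) keeps the
    shift comparable to the raw-count convention.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    df = cm.data.astype(float)
    out = np.log10(df + pseudocount) - np.log10(pseudocount)
    return CountMatrix(out, ValueKind.TRANSFORMED)


def row_normalize(cm: CountMatrix, lineage_samples: list[str]) -> CountMatrix:
    """Row-normalize across a lineage subset: produces P_bc.

    The matrix must already be column-normalized (the per-sample read-depth
    correction); each barcode row over ``lineage_samples`` is then divided
    by its row total so rows sum to 1. Zero rows cannot be normalized and
    are dropped with a warning.
    """
    if not lineage_samples:
        raise ValueError("lineage subset must be nonempty")
    if cm.value_kind not in (ValueKind.NORMALIZED, ValueKind.TRANSFORMED):
        raise ValueError("row_normalize expects a column-normalized matrix")
    missing = [s for s in lineage_samples if s not in cm.data.columns]
    if missing:
        raise KeyError(f"unknown sample(s): {missing}")
    sub = cm.data[list(lineage_samples)].astype(float)
    totals = sub.sum(axis=1)
    dropped = totals[totals == 0].index.tolist()
    if dropped:
        warnings.warn(f"dropping {len(dropped)} all-zero barcode row(s)")
        sub = sub.loc[totals > 0]
        totals = totals[totals > 0]
    if sub.shape[0] == 0:
        raise ValueError("no barcode has positive abundance in the subset")
    out = sub.div(totals, axis=0)
    return CountMatrix(out, ValueKind.TRANSFORMED)
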