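"""Experiment-level quality control.

Two technical confounders dominate cellular-barcoding experiments:

* **PCR/sequencing noise** — each lysed sample is split and amplified twice
  (duplicates ``dupA``/``dupB``); low correlation between the two halves
  flags amplification artefacts. Barcodes seen in only one of the two
  duplicates are treated as noise and zeroed before duplicates are merged.
* **Repeat use** — a finite barcode library means the same tag can label
  founder cells in different individuals; such barcodes show up as sharing
  between separately transplanted individuals and confound clonal identity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import CountMatrix, MetadataTable, ValidationReport, ValueKind

__all__ = [
    "DuplicatePair",
    "CorrelationResult",
    "RepeatUseSummary",
    "make_duplicate_pairs",
    "duplicate_correlation",
    "merge_duplicates",
    "merged_metadata",
    "repeat_use_matrix",
    "repeat_use_frequency",
]

DUPLICATE_VAR = "duplicate"


@dataclass
class DuplicatePair:
    """Aligned abundances of one sample's two technical duplicates.

    Restricted to the union of barcodes nonzero in at least one duplicate:
    doubly-zero barcodes carry no information and would inflate correlation.
    """

    sample_base: str
    barcode_ids: list[str]
    values_a: np.ndarray
    values_b: np.ndarray

    def __post_init__(self) -> None:
        self.values_a = np.asarray(self.values_a, dtype=float)
        self.values_b = np.asarray(self.values_b, dtype=float)
        if len(self.values_a) != len(self.values_b) or len(self.values_a) < 1:
            raise ValueError("duplicate vectors must be aligned and nonempty")
        if ((self.values_a == 0) & (self.values_b == 0)).any():
            raise ValueError("doubly-zero barcode in DuplicatePair")


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    method: str
    n: int


@dataclass
class RepeatUseSummary:
    """Cross-individual barcode sharing.

    ``sharing_matrix[i, j]`` counts unique barcodes detected in both
    individuals i and j (diagonal = per-individual richness); ``frequency``
    is the fraction of detected barcodes found in more than one individual.
    """

    sharing_matrix: pd.DataFrame
    frequency: float


def _base_names(md: MetadataTable, duplicate_var: str) -> pd.Series:
    """Map each sample id to its duplicate-free base name.

    If the sample id ends with ``_<duplicate label>`` the suffix is
    stripped; otherwise the base is the underscore-join of the remaining
    metadata variables.
    """
    bases = {}
    for sid in md.sample_ids:
        dup = md.data.loc[sid, duplicate_var]
        suffix = f"_{dup}"
        if sid.endswith(suffix):
            bases[sid] = sid[: -len(suffix)]
        else:
            other = [v for v in md.variables if v != duplicate_var]
            bases[sid] = "_".join(str(md.data.loc[sid, v]) for v in other)
    return pd.Series(bases)


def make_duplicate_pairs(
    cm: CountMatrix, md: MetadataTable, duplicate_var: str = DUPLICATE_VAR
) -> list[DuplicatePair]:
    """Pair duplicate columns of ``cm`` by their base sample name."""
    if duplicate_var not in md.variables:
        raise ValueError(f"metadata has no {duplicate_var!r} variable")
    bases = _base_names(md, duplicate_var)
    pairs: list[DuplicatePair] = []
    for base in pd.unique(bases.loc[cm.sample_ids]):
        members = [s for s in cm.sample_ids if bases[s] == base]
        if len(members) != 2:
            if len(members) == 1:
                raise ValueError(f"unpaired duplicate {members[0]}")
            raise ValueError(
                f"sample base {base!r} has {len(members)} duplicates, expected 2"
            )
        order = sorted(members, key=lambda s: md.data.loc[s, duplicate_var])
        a = cm.data[order[0]].to_numpy(dtype=float)
        b = cm.data[order[1]].to_numpy(dtype=float)
        keep = (a > 0) | (b > 0)
        pairs.append(
            DuplicatePair(
                sample_base=base,
                barcode_ids=[bc for bc, k in zip(cm.barcode_ids, keep) if k],
                values_a=a[keep],
                values_b=b[keep],
            )
        )
    return pairs


def duplicate_correlation(
    pair: DuplicatePair, method: str = "spearman"
) -> CorrelationResult:
    """Correlation between the two duplicates of one sample.

    Spearman uses average ranks for ties; p-values are the asymptotic
    approximations. A constant vector makes the coefficient undefined: it
    is reported as NaN with a warning, never raised.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown correlation method {method!r}")
    a, b = pair.values_a, pair.values_b
    n = len(a)
    if n < 2:
        warnings.warn(f"{pair.sample_base}: <2 barcodes, correlation undefined")
        return CorrelationResult(float("nan"), float("nan"), method, n)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn(f"{pair.sample_base}: constant duplicate, correlation undefined")
        return CorrelationResult(float("nan"), float("nan"), method, n)
    if method == "spearman":
        res = stats.spearmanr(a, b)
    else:
        res = stats.pearsonr(a, b)
    return CorrelationResult(float(res.statistic), float(res.pvalue), method, n)


def merge_duplicates(
    cm: CountMatrix,
    md: MetadataTable,
    min_pearson: float = 0.8,
    combine: str = "sum",
    duplicate_var: str = DUPLICATE_VAR,
    drop_failing: bool = False,
) -> tuple[CountMatrix, ValidationReport]:
    """Filter and merge technical duplicates into one column per sample.

    The three steps, applied per duplicate pair:

    1. pairs whose Pearson correlation (on column-normalized values over
       the union of nonzero barcodes) is not above ``min_pearson`` are
       flagged in the report (and dropped only if ``drop_failing``);
    2. each barcode nonzero in exactly one duplicate is set to zero in
       both (singleton zeroing);
    3. duplicates are combined (``sum`` or ``mean``) and the resulting
       columns renormalized to sum to 1.
    """
    if not -1.0 <= min_pearson <= 1.0:
        raise ValueError("min_pearson must be in [-1, 1]")
    if combine not in ("sum", "mean"):
        raise ValueError(f"unknown combine mode {combine!r}")

    report = ValidationReport()
    # correlations are computed on within-column proportions so the filter
    # does not depend on sequencing depth differences between duplicates
    colsums = cm.data.sum(axis=0)
    norm = cm.data.div(colsums.where(colsums > 0, 1.0), axis=1)
    norm_cm = CountMatrix(norm, ValueKind.NORMALIZED)
    pairs = make_duplicate_pairs(norm_cm, md, duplicate_var)

    merged_cols: dict[str, np.ndarray] = {}
    for pair in pairs:
        corr = duplicate_correlation(pair, method="pearson")
        passed = corr.rho > min_pearson if np.isfinite(corr.rho) else False
        if not passed:
            report.add(
                "warning",
                pair.sample_base,
                f"duplicate Pearson correlation {corr.rho:.4g} not above "
                f"{min_pearson:g}; failing QC",
            )
            if drop_failing:
                continue
        else:
            report.add(
                "info", pair.sample_base, f"duplicate Pearson correlation {corr.rho:.4g}"
            )
        a = np.zeros(cm.shape[0])
        b = np.zeros(cm.shape[0])
        idx = cm.data.index.get_indexer(pair.barcode_ids)
        a[idx] = pair.values_a
        b[idx] = pair.values_b
        singleton = (a > 0) != (b > 0)
        a[singleton] = 0.0
        b[singleton] = 0.0
        merged = a + b if combine == "sum" else (a + b) / 2.0
        merged_cols[pair.sample_base] = merged

    if not merged_cols:
        raise ValueError("no duplicate pairs left after filtering")
    out = pd.DataFrame(merged_cols, index=cm.data.index)
    sums = out.sum(axis=0)
    zero_cols = sums[sums == 0].index.tolist()
    for col in zero_cols:
        report.add("warning", col, "merged sample has no surviving barcodes")
    out = out.div(sums.where(sums > 0, 1.0), axis=1)
    return CountMatrix(out, ValueKind.NORMALIZED), report


def merged_metadata(
    md: MetadataTable, duplicate_var: str = DUPLICATE_VAR
) -> MetadataTable:
    """Metadata for merged samples: duplicate variable dropped, one row per base."""
    if duplicate_var not in md.variables:
        raise ValueError(f"metadata has no {duplicate_var!r} variable")
    bases = _base_names(md, duplicate_var)
    keep = [v for v in md.variables if v != duplicate_var]
    df = md.data[keep].copy()
    df.index = bases.loc[df.index]
    df = df[~df.index.duplicated()]
    df.index.name = "sample"
    return MetadataTable(df)


def repeat_use_matrix(
    cm: CountMatrix,
    md: MetadataTable,
    group_var: str = "individual",
    min_reads: float = 0.0,
) -> RepeatUseSummary:
    """Quantify barcode sharing between individuals.

    A barcode counts as detected in an individual if its abundance exceeds
    ``min_reads`` in at least one of that individual's samples. The
    frequency denominator is the union of detected barcodes across the
    compared individuals.
    """
    if group_var not in md.variables:
        raise ValueError(f"metadata has no {group_var!r} variable")
    groups = md.levels(group_var)
    if len(groups) < 2:
        raise ValueError("repeat use needs >=2 individuals")
    detected = {}
    for g in groups:
        samples = [s for s in md.samples_where(**{group_var: g}) if s in cm.data.columns]
        if not samples:
            detected[g] = np.zeros(cm.shape[0], dtype=bool)
            continue
        detected[g] = (cm.data[samples].to_numpy() > min_reads).any(axis=1)
    mat = pd.DataFrame(
        {
            gi: [int((detected[gi] & detected[gj]).sum()) for gj in groups]
            for gi in groups
        },
        index=groups,
    ).T
    n_individuals = np.sum([detected[g] for g in groups], axis=0)
    union = int((n_individuals >= 1).sum())
    shared = int((n_individuals >= 2).sum())
    freq = shared / union if union else 0.0
    return RepeatUseSummary(sharing_matrix=mat, frequency=freq)


def repeat_use_frequency(summary: RepeatUseSummary) -> float:
    """Repeat-use frequency as a percentage of detected barcodes."""
    return 100.0 * summary.frequency
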