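"""Clonal fate analyses: barcode sharing, lineage bias, clustering.

Sharing asks the binary question — which barcodes appear in one cell type,
the other, or both. The threshold classifier refines it: after column
normalization (per-sample read depth) and row normalization (each barcode's
distribution across the selected cell types, P_bc), a barcode is assigned
to every lineage where its proportion meets the threshold t. t = 0 reduces
to presence/absence; t > 0.5 forces a single lineage per barcode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .datamodel import CountMatrix, MetadataTable
from .transform import arcsin_sqrt, log_transform, normalize_columns

__all__ = [
    "pairwise_abundance",
    "SharingBreakdown",
    "sharing_breakdown",
    "ternary_abundance",
    "BiasTable",
    "BiasAssignment",
    "bias_table",
    "classify_lineage_bias",
    "category_summary",
    "HeatmapResult",
    "heatmap_matrix",
    "correlogram_matrix",
]

_POOLED = "__pooled__"


def _level_abundance(
    cm: CountMatrix,
    md: MetadataTable,
    var: str,
    level: str,
    samples: list[str] | None = None,
) -> pd.Series:
    """Mean within-sample proportion of each barcode over a level's samples.

    The mean (not the sum) keeps values on the proportion scale [0, 1] so
    the arcsine transform stays applicable when a level spans several
    samples.
    """
    if var not in md.variables:
        raise ValueError(f"metadata has no {var!r} variable")
    if level not in md.levels(var):
        raise ValueError(f"unknown level {level!r} of variable {var!r}")
    pool = md.samples_where(**{var: level})
    if samples is not None:
        pool = [s for s in pool if s in samples]
    pool = [s for s in pool if s in cm.data.columns]
    if not pool:
        raise ValueError(f"no samples of {var}={level} in the count matrix")
    norm = normalize_columns(cm) if cm.value_kind.value != "normalized" else cm
    return norm.data[pool].mean(axis=1)


def _apply_scale(values: pd.DataFrame, transform: str) -> pd.DataFrame:
    if transform == "none":
        return values
    if transform == "arcsin":
        return np.arcsin(np.sqrt(values.clip(0.0, 1.0)))
    if transform == "log":
        pseudo = 1e-5  # one read at a typical 1e5 depth
        return np.log10(values + pseudo) - np.log10(pseudo)
    raise ValueError(f"unknown transform {transform!r}")


def pairwise_abundance(
    cm: CountMatrix,
    md: MetadataTable,
    var: str,
    level_a: str,
    level_b: str,
    transform: str = "none",
    individual_var: str | None = None,
) -> pd.DataFrame:
    """Dotplot table: per barcode, abundance in two levels of a variable.

    Returns columns (barcode, x, y[, individual]); barcodes zero in both
    levels are excluded. With ``individual_var``, one row per barcode per
    individual (the per-individual tables the sharing summary averages).
    """
    groups: list[tuple[str, list[str] | None]]
    if individual_var is None:
        groups = [(_POOLED, None)]
    else:
        groups = [
            (ind, md.samples_where(**{individual_var: ind}))
            for ind in md.levels(individual_var)
        ]
    frames = []
    for label, samples in groups:
        x = _level_abundance(cm, md, var, level_a, samples)
        y = _level_abundance(cm, md, var, level_b, samples)
        keep = (x > 0) | (y > 0)
        df = pd.DataFrame(
            {
                "barcode": x.index[keep],
                "x": _apply_scale(x[keep].to_frame(), transform).iloc[:, 0].to_numpy(),
                "y": _apply_scale(y[keep].to_frame(), transform).iloc[:, 0].to_numpy(),
            }
        )
        if individual_var is not None:
            df["individual"] = label
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


@dataclass
class SharingBreakdown:
    """Percentages of barcodes private to each level or shared.

    ``pooled`` pools barcodes across individuals; ``per_individual_mean``
    averages each individual's percentages (with their SD).
    """

    categories: dict[str, float]
    mode: str
    sd: dict[str, float] | None = None

    def __post_init__(self) -> None:
        total = sum(self.categories.values())
        if abs(total - 100.0) > 1e-9:
            raise ValueError(f"sharing percentages sum to {total}, not 100")


def _presence_percentages(table: pd.DataFrame) -> dict[str, float]:
    x = table["x"].to_numpy() > 0
    y = table["y"].to_numpy() > 0
    n = len(table)
    return {
        "only_a": 100.0 * (x & ~y).sum() / n,
        "only_b": 100.0 * (~x & y).sum() / n,
        "shared": 100.0 * (x & y).sum() / n,
    }


def sharing_breakdown(
    pair_table: pd.DataFrame, mode: str = "pooled"
) -> SharingBreakdown:
    """Shared/unshared barcode percentages from a dotplot table.

    ``pooled`` counts each (barcode, individual) detection once over the
    whole table; ``per_individual_mean`` requires an ``individual`` column
    and reports the mean and SD of the per-individual percentages.
    """
    if len(pair_table) == 0:
        raise ValueError("empty pair table")
    if mode == "pooled":
        return SharingBreakdown(_presence_percentages(pair_table), mode)
    if mode != "per_individual_mean":
        raise ValueError(f"unknown sharing mode {mode!r}")
    if "individual" not in pair_table.columns:
        raise ValueError("per_individual_mean needs an 'individual' column")
    per_ind = [
        _presence_percentages(sub) for _, sub in pair_table.groupby("individual", sort=False)
    ]
    keys = ("only_a", "only_b", "shared")
    means = {k: float(np.mean([p[k] for p in per_ind])) for k in keys}
    sds = {k: float(np.std([p[k] for p in per_ind], ddof=1)) if len(per_ind) > 1 else 0.0 for k in keys}
    return SharingBreakdown(means, mode, sd=sds)


def ternary_abundance(
    cm: CountMatrix,
    md: MetadataTable,
    var: str,
    levels: tuple[str, str, str],
) -> pd.DataFrame:
    """Ternary-plot table over exactly three levels.

    Per barcode: row-normalized coordinates (p1+p2+p3 = 1) plus the total
    abundance for dot sizing; barcodes zero across all three are excluded
    with a warning.
    """
    if len(levels) != 3:
        raise ValueError("ternary plots need exactly three levels")
    cols = {lv: _level_abundance(cm, md, var, lv) for lv in levels}
    df = pd.DataFrame(cols)
    total = df.sum(axis=1)
    dropped = int((total == 0).sum())
    if dropped:
        warnings.warn(f"excluding {dropped} barcode(s) zero in all three levels")
    df = df.loc[total > 0]
    total = total[total > 0]
    out = df.div(total, axis=0)
    out.columns = [f"p_{lv}" for lv in levels]
    out.insert(0, "barcode", out.index)
    out["total"] = total
    return out.reset_index(drop=True)


@dataclass
class BiasTable:
    """Per-individual lineage-output matrices for the bias classifier.

    For each individual: R = column-normalized read abundance of each
    barcode in each lineage (depth-corrected), and P = R row-normalized so
    each barcode's row sums to 1 (the proportions the threshold applies to).
    Barcodes with zero total across the lineages are excluded (they cannot
    be row-normalized).
    """

    lineages: list[str]
    R: dict[str, pd.DataFrame] = field(default_factory=dict)
    P: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def individuals(self) -> list[str]:
        return list(self.R)


@dataclass(frozen=True)
class BiasAssignment:
    barcode_id: str
    individual: str
    category: frozenset[str]
    threshold: float

    @property
    def label(self) -> str:
        if not self.category:
            return "unclassified"
        return "+".join(sorted(self.category))


def bias_table(
    cm: CountMatrix,
    md: MetadataTable,
    lineage_var: str = "cell_type",
    lineages: list[str] | None = None,
    individual_var: str | None = "individual",
) -> BiasTable:
    """Build R and P matrices per individual from a merged count matrix.

    Column normalization happens first (within each sample), then abundances
    are averaged over any replicate samples of the same (individual,
    lineage), then rows are normalized within each individual.
    """
    if lineage_var not in md.variables:
        raise ValueError(f"metadata has no {lineage_var!r} variable")
    lineages = list(lineages) if lineages else md.levels(lineage_var)
    if individual_var is not None and individual_var in md.variables:
        individuals = md.levels(individual_var)
    else:
        individual_var, individuals = None, [_POOLED]
    bt = BiasTable(lineages=lineages)
    for ind in individuals:
        samples = None if individual_var is None else md.samples_where(**{individual_var: ind})
        cols = {}
        for lv in lineages:
            try:
                cols[lv] = _level_abundance(cm, md, lineage_var, lv, samples)
            except ValueError:
                cols[lv] = pd.Series(0.0, index=cm.data.index)
        R = pd.DataFrame(cols)
        totals = R.sum(axis=1)
        R = R.loc[totals > 0]
        if R.empty:
            continue
        bt.R[ind] = R
        bt.P[ind] = R.div(R.sum(axis=1), axis=0)
    if not bt.R:
        raise ValueError("no barcode has positive abundance in the selected lineages")
    return bt


def classify_lineage_bias(bias: BiasTable, t: float) -> list[BiasAssignment]:
    """Assign each barcode the set of lineages where P_bc >= t (and > 0).

    The extra P_bc > 0 condition makes t = 0 mean presence/absence rather
    than assigning every lineage to every barcode. Barcodes whose category
    would be empty (possible only for t > 0 when no single lineage reaches
    it — impossible for two lineages, possible for three or more) are
    returned with an empty category and reported by their ``label``.
    """
    if not 0.0 <= t < 1.0:
        raise ValueError("threshold must be in [0, 1)")
    out: list[BiasAssignment] = []
    for ind, P in bias.P.items():
        vals = P.to_numpy()
        hits = (vals >= t) & (vals > 0)
        for i, bc in enumerate(P.index):
            category = frozenset(np.asarray(bias.lineages)[hits[i]])
            out.append(BiasAssignment(str(bc), ind, category, t))
    return out


def category_summary(
    assignments: list[BiasAssignment], bias: BiasTable
) -> pd.DataFrame:
    """Barcode counts and lineage contributions per bias category.

    Rows: one per category label. ``n_barcodes`` counts assignments across
    individuals; each lineage column is the percentage of that lineage's
    classified abundance contributed by the category's barcodes, averaged
    over individuals (so per lineage the column sums to 100).
    """
    if not assignments:
        raise ValueError("no assignments")
    thresholds = {a.threshold for a in assignments}
    if len(thresholds) > 1:
        raise ValueError("assignments mix thresholds")
    by_ind: dict[str, list[BiasAssignment]] = {}
    for a in assignments:
        by_ind.setdefault(a.individual, []).append(a)
    labels = sorted({a.label for a in assignments})
    counts = {lab: 0 for lab in labels}
    contrib_per_ind: dict[str, list[pd.Series]] = {lab: [] for lab in labels}
    for ind, asgn in by_ind.items():
        R = bias.R[ind]
        lineage_totals = R.sum(axis=0)
        for lab in labels:
            bcs = [a.barcode_id for a in asgn if a.label == lab]
            counts[lab] += len(bcs)
            if lineage_totals.gt(0).any():
                summed = R.loc[R.index.intersection(bcs)].sum(axis=0)
                pct = 100.0 * summed / lineage_totals.where(lineage_totals > 0, np.nan)
                contrib_per_ind[lab].append(pct)
    rows = []
    for lab in labels:
        contribs = (
            pd.concat(contrib_per_ind[lab], axis=1).mean(axis=1)
            if contrib_per_ind[lab]
            else pd.Series(np.nan, index=bias.lineages)
        )
        rows.append([lab, counts[lab], *[contribs.get(lv, np.nan) for lv in bias.lineages]])
    return pd.DataFrame(rows, columns=["category", "n_barcodes", *bias.lineages])


@dataclass
class HeatmapResult:
    matrix: pd.DataFrame          # transformed values, original row order
    row_order: list[str]          # dendrogram leaf order
    col_order: list[str]
    row_linkage: np.ndarray       # scipy linkage matrix
    col_linkage: np.ndarray | None = None


def _transform_for_heatmap(cm: CountMatrix, transform: str) -> pd.DataFrame:
    norm = normalize_columns(cm) if cm.value_kind.value != "normalized" else cm
    if transform == "arcsin":
        return arcsin_sqrt(norm).data
    if transform == "log":
        return log_transform(norm, pseudocount=1e-5).data
    if transform == "none":
        return norm.data
    raise ValueError(f"unknown transform {transform!r}")


def heatmap_matrix(
    cm: CountMatrix,
    md: MetadataTable | None = None,
    transform: str = "arcsin",
    distance: str = "euclidean",
    linkage: str = "complete",
    cluster_columns: bool = False,
) -> HeatmapResult:
    """Agglomerative clustering of barcode rows for heatmap display.

    Rows are clustered on the transformed proportions (arcsine by default);
    columns keep their metadata order unless ``cluster_columns``. Rows are
    pre-sorted by barcode id so the linkage is reproducible regardless of
    input order. All-zero rows are dropped with a warning.
    """
    df = _transform_for_heatmap(cm, transform)
    nonzero = df.sum(axis=1) > 0
    if (~nonzero).any():
        warnings.warn(f"dropping {int((~nonzero).sum())} all-zero row(s) before clustering")
        df = df.loc[nonzero]
    df = df.sort_index(kind="stable")
    if df.shape[0] < 2:
        raise ValueError("clustering needs at least 2 nonzero rows")
    Z = hierarchy.linkage(pdist(df.to_numpy(), metric=distance), method=linkage)
    row_order = [df.index[i] for i in hierarchy.leaves_list(Z)]
    col_linkage = None
    col_order = list(df.columns)
    if cluster_columns and df.shape[1] >= 2:
        col_linkage = hierarchy.linkage(pdist(df.to_numpy().T, metric=distance), method=linkage)
        col_order = [df.columns[i] for i in hierarchy.leaves_list(col_linkage)]
    return HeatmapResult(df, row_order, col_order, Z, col_linkage)


def correlogram_matrix(
    cm: CountMatrix,
    md: MetadataTable,
    var: str,
    method: str = "spearman",
) -> pd.DataFrame:
    """Pairwise correlation of barcode abundances between levels of a variable.

    Each pair is correlated over the union of barcodes nonzero in either
    level; entries with fewer than 2 such barcodes are NaN with a warning.
    Diagonal is 1.
    """
    levels = md.levels(var)
    if len(levels) < 2:
        raise ValueError("correlogram needs >=2 levels")
    ab = {lv: _level_abundance(cm, md, var, lv) for lv in levels}
    out = pd.DataFrame(np.eye(len(levels)), index=levels, columns=levels)
    fn = stats.spearmanr if method == "spearman" else stats.pearsonr
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown correlation method {method!r}")
    for i, a in enumerate(levels):
        for b in levels[i + 1:]:
            x, y = ab[a], ab[b]
            keep = (x > 0) | (y > 0)
            if keep.sum() < 2 or np.ptp(x[keep]) == 0 or np.ptp(y[keep]) == 0:
                warnings.warn(f"correlation undefined for pair ({a}, {b})")
                rho = np.nan
            else:
                rho = float(fn(x[keep], y[keep]).statistic)
            out.loc[a, b] = out.loc[b, a] = rho
    return out
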