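"""Clonal diversity and clone-size distributions.

Diversity answers "how many progenitors contribute to this sample":
richness counts unique clones, Shannon entropy H = -sum p ln p (nats) and
the Gini-Simpson index D = 1 - sum p^2 weight clones by how evenly they
contribute. Clone-size diagrams answer "how unequal are the clones": a
cumulative share curve that bows far above the diagonal means a few large
clones dominate; the diagonal itself means equal contributions.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd

from .datamodel import CountMatrix, MetadataTable

__all__ = [
    "diversity",
    "diversity_by_group",
    "CumulativeCurve",
    "cumulative_curve",
    "top_share",
    "clone_size_distribution",
]

METRICS = ("richness", "shannon", "simpson", "inverse_simpson")


def _proportions(abundances: np.ndarray) -> np.ndarray:
    x = np.asarray(abundances, dtype=float)
    if x.ndim != 1:
        raise ValueError("abundance vector must be one-dimensional")
    if (x < 0).any():
        raise ValueError("abundances must be nonnegative")
    total = x.sum()
    if total == 0:
        raise ValueError("no clones detected")
    return x[x > 0] / total


def diversity(abundances: np.ndarray, metric: str = "shannon") -> float:
    """Diversity of one sample's clone-abundance vector.

    richness: number of clones with positive abundance.
    shannon: H = -sum p ln p in nats; ln(richness) for a uniform sample.
    simpson: Gini-Simpson 1 - sum p^2 in [0, 1 - 1/richness].
    inverse_simpson: 1 / sum p^2.
    All but richness are scale-invariant (computed on proportions).
    """
    if metric not in METRICS:
        raise ValueError(f"unknown diversity metric {metric!r}")
    p = _proportions(abundances)
    if metric == "richness":
        return float(len(p))
    if metric == "shannon":
        return float(-(p * np.log(p)).sum())
    if metric == "simpson":
        return float(1.0 - (p**2).sum())
    return float(1.0 / (p**2).sum())


def diversity_by_group(
    cm: CountMatrix,
    md: MetadataTable,
    group_vars: list[str],
    metric: str = "shannon",
) -> pd.DataFrame:
    """Per-sample diversity labeled by metadata groups (boxplot substrate).

    Returns one row per sample with its group values and the diversity
    value; all-zero samples get NaN.
    """
    for v in group_vars:
        if v not in md.variables:
            raise ValueError(f"metadata has no {v!r} variable")
    rows = []
    for sid in cm.sample_ids:
        col = cm.data[sid].to_numpy(dtype=float)
        value = diversity(col, metric) if col.sum() > 0 else float("nan")
        labels = [md.data.loc[sid, v] for v in group_vars] if sid in md.data.index else [None] * len(group_vars)
        rows.append([sid, *labels, value])
    return pd.DataFrame(rows, columns=["sample", *group_vars, metric])


@dataclass
class CumulativeCurve:
    """Cumulative clone-share curve, clones sorted by descending abundance.

    ``ranks[k-1] = k/n`` and ``shares[k-1]`` = summed share of the top k
    clones; both end at 1 and the shares are concave by construction.
    """

    ranks: np.ndarray
    shares: np.ndarray


def _sorted_positive(abundances, ids=None) -> np.ndarray:
    x = np.asarray(abundances, dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be nonnegative")
    if ids is None:
        ids = np.arange(len(x))
    ids = np.asarray(ids)
    keep = x > 0
    if not keep.any():
        raise ValueError("no clones detected")
    x, ids = x[keep], ids[keep]
    # descending abundance, ties broken by id for determinism
    order = np.lexsort((ids, -x))
    return x[order]


def cumulative_curve(abundances, ids=None) -> CumulativeCurve:
    """Cumulative diagram: point k is (k/n, share of top-k clones)."""
    x = _sorted_positive(abundances, ids)
    n = len(x)
    shares = np.cumsum(x) / x.sum()
    ranks = np.arange(1, n + 1) / n
    return CumulativeCurve(ranks=ranks, shares=shares)


def top_share(
    abundances, k: int | None = None, q: float | None = None, ids=None
) -> float:
    """Percentage of total abundance held by the largest clones.

    Either the top ``k`` clones or the top ``ceil(q * n)`` clones, with
    ``q`` a fraction of the positive-clone count.
    """
    x = _sorted_positive(abundances, ids)
    n = len(x)
    if (k is None) == (q is None):
        raise ValueError("give exactly one of k or q")
    if k is not None:
        if k < 1:
            raise ValueError("k must be a positive integer")
        if k > n:
            raise ValueError(f"k={k} exceeds the {n} positive clones")
    else:
        if not 0 < q <= 1:
            raise ValueError("q must be in (0, 1]")
        k = ceil(q * n)
    return float(100.0 * x[:k].sum() / x.sum())


def clone_size_distribution(
    abundances, bins: int = 10, log_axis: bool = False
) -> pd.DataFrame:
    """Histogram of positive clone sizes (optionally log10-spaced bins).

    Returns a table of (bin_left, bin_right, count); counts sum to the
    number of positive clones.
    """
    if bins < 1:
        raise ValueError("bins must be >= 1")
    x = np.asarray(abundances, dtype=float)
    x = x[x > 0]
    if len(x) == 0:
        raise ValueError("no clones detected")
    if log_axis:
        edges = np.logspace(np.log10(x.min()), np.log10(x.max()), bins + 1)
        edges[0] *= 1 - 1e-12  # keep the minimum inside the first bin
    else:
        edges = np.linspace(x.min(), x.max(), bins + 1)
    counts, edges = np.histogram(x, bins=edges)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
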