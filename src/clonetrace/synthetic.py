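"""Generative model of a cellular-barcoding experiment with known truth.

The generator emulates the statistical structure the analyses assume:

* a finite barcode library of size L sampled with replacement, so the same
  tag can label founder clones in several individuals (repeat use);
* per-clone fate categories (lineage-restricted or multi-outcome) with
  Dirichlet-distributed output proportions across lineages;
* log-normal clone sizes (total output cells per founder);
* per-sample sequencing as multinomial read draws at a fixed depth, done
  independently for each technical duplicate, optionally overdispersed
  (Dirichlet-multinomial, modeling PCR jackpotting) and thinned by a
  per-duplicate detection-failure (dropout) probability.

One seed drives library draws, fates, sizes and reads in a fixed order, so
identical configurations reproduce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .datamodel import CountMatrix, MetadataTable, ValueKind

__all__ = [
    "FateCategory",
    "SimConfig",
    "SimTruth",
    "simulate_experiment",
    "expected_repeat_use",
    "sample_repeat_use_frequency",
]


@dataclass(frozen=True)
class FateCategory:
    """One clone-fate class: its prior probability and output model.

    ``alpha`` is either a one-hot vector over the lineages (deterministic
    lineage-restricted output) or a positive Dirichlet concentration from
    which the clone's true output proportions are drawn.
    """

    name: str
    probability: float
    alpha: tuple[float, ...]


def default_fate_model(lineages: tuple[str, ...]) -> tuple[FateCategory, ...]:
    """Uni-outcome categories per lineage plus one multi-outcome class.

    Two lineages: 30% restricted to each, 40% bi-outcome with Dirichlet(2,2)
    outputs (unbalanced bi-outcome clones are common, balanced ones are
    not rare). More lineages split the same 60/40 restricted/multi mix.
    """
    k = len(lineages)
    uni = 0.6 / k
    cats = [
        FateCategory(f"uni_{lv}", uni, tuple(1.0 if j == i else 0.0 for j in range(k)))
        for i, lv in enumerate(lineages)
    ]
    cats.append(FateCategory("multi", 0.4, tuple(2.0 for _ in range(k))))
    return tuple(cats)


@dataclass
class SimConfig:
    """Study conditions for one simulated experiment."""

    seed: int = 0
    n_individuals: int = 3
    n_clones_per_individual: int = 30
    library_size: int = 1000
    lineages: tuple[str, ...] = ("cDC1", "cDC2")
    fate_model: tuple[FateCategory, ...] | None = None
    clone_size_mu: float = 5.0      # ln-scale mean of total output cells
    clone_size_sigma: float = 1.0   # ln-scale SD (clone sizes are highly skewed)
    read_depth: int = 100_000       # reads per duplicate per sample
    dropout: float = 0.02           # per-duplicate per-clone detection failure
    overdispersion: float | None = None  # Dirichlet-multinomial precision; None = multinomial
    duplicate_labels: tuple[str, str] = ("dupA", "dupB")
    exact: bool = False             # expected counts instead of sampled reads

    def __post_init__(self) -> None:
        if self.fate_model is None:
            self.fate_model = default_fate_model(self.lineages)
        probs = [c.probability for c in self.fate_model]
        if abs(sum(probs) - 1.0) > 1e-9 or min(probs) < 0:
            raise ValueError("fate-category probabilities must sum to 1")
        for cat in self.fate_model:
            if len(cat.alpha) != len(self.lineages):
                raise ValueError(
                    f"category {cat.name!r} has {len(cat.alpha)} concentrations "
                    f"for {len(self.lineages)} lineages"
                )
        if self.library_size < 1:
            raise ValueError("library_size must be >= 1")
        if self.read_depth < 0 or not 0.0 <= self.dropout <= 1.0:
            raise ValueError("read_depth must be >= 0 and dropout in [0, 1]")


@dataclass
class SimTruth:
    """Ground truth: one row per founder clone, plus repeat-use labels.

    ``clones`` columns: individual, barcode, category, size, and one true
    output proportion per lineage. ``repeat_used`` holds barcodes drawn in
    more than one individual (the cross-individual confounder the QC
    estimates); ``multi_clone`` holds barcodes drawn by more than one clone
    anywhere, including within one individual.
    """

    clones: pd.DataFrame
    repeat_used: frozenset[str] = field(default_factory=frozenset)
    multi_clone: frozenset[str] = field(default_factory=frozenset)


def _draw_library_barcodes(
    rng: np.random.Generator, library_size: int, n_per_individual: list[int]
) -> list[np.ndarray]:
    """Uniform draws with replacement from the library, one array per individual."""
    return [rng.integers(0, library_size, size=n) for n in n_per_individual]


def _barcode_name(index: int, library_size: int) -> str:
    width = max(4, len(str(library_size - 1)))
    return f"LIB{index:0{width}d}"


def simulate_experiment(
    cfg: SimConfig,
) -> tuple[SimTruth, CountMatrix, MetadataTable]:
    """Simulate duplicate-level counts, metadata and full ground truth.

    Samples are named ``<individual>_<lineage>_<dup>`` with metadata
    variables (individual, cell_type, duplicate). Reproducible under a
    fixed seed.
    """
    if len(set(cfg.lineages)) != len(cfg.lineages) or not cfg.lineages:
        raise ValueError("lineages must be nonempty and unique")
    rng = np.random.default_rng(cfg.seed)
    individuals = [f"m{i + 1}" for i in range(cfg.n_individuals)]
    draws = _draw_library_barcodes(
        rng, cfg.library_size, [cfg.n_clones_per_individual] * cfg.n_individuals
    )
    cat_probs = np.array([c.probability for c in cfg.fate_model])
    clone_rows = []
    for ind, bcs in zip(individuals, draws):
        n = len(bcs)
        cats = rng.choice(len(cfg.fate_model), size=n, p=cat_probs)
        sizes = rng.lognormal(cfg.clone_size_mu, cfg.clone_size_sigma, size=n)
        for bc, ci, size in zip(bcs, cats, sizes):
            cat = cfg.fate_model[ci]
            alpha = np.asarray(cat.alpha, dtype=float)
            if np.count_nonzero(alpha) == 1:
                props = (alpha > 0).astype(float)
            else:
                props = rng.dirichlet(alpha)
            clone_rows.append(
                [ind, _barcode_name(int(bc), cfg.library_size), cat.name, float(size), *props]
            )
    clones = pd.DataFrame(
        clone_rows,
        columns=["individual", "barcode", "category", "size", *cfg.lineages],
    )

    seen_in = clones.groupby("barcode")["individual"].nunique()
    repeat_used = frozenset(seen_in.index[seen_in > 1])
    n_clones = clones.groupby("barcode").size()
    multi_clone = frozenset(n_clones.index[n_clones > 1])

    all_barcodes = sorted(clones["barcode"].unique())
    bc_index = {bc: i for i, bc in enumerate(all_barcodes)}
    counts: dict[str, np.ndarray] = {}
    meta_rows: dict[str, list[str]] = {}
    for ind in individuals:
        sub = clones[clones["individual"] == ind]
        rows = np.array([bc_index[bc] for bc in sub["barcode"]])
        sizes = sub["size"].to_numpy()
        for lv in cfg.lineages:
            weights = sizes * sub[lv].to_numpy()
            sample_base = f"{ind}_{lv}"
            for dup in cfg.duplicate_labels:
                col = np.zeros(len(all_barcodes))
                if weights.sum() > 0:
                    w = weights.copy()
                    if cfg.dropout > 0 and not cfg.exact:
                        w = w * (rng.random(len(w)) >= cfg.dropout)
                    if w.sum() > 0:
                        p = w / w.sum()
                        if cfg.exact:
                            reads = cfg.read_depth * p
                        else:
                            if cfg.overdispersion is not None:
                                nz = p > 0
                                p = p.copy()
                                p[nz] = rng.dirichlet(p[nz] * cfg.overdispersion)
                            reads = rng.multinomial(cfg.read_depth, p).astype(float)
                        np.add.at(col, rows, reads)
                sid = f"{sample_base}_{dup}"
                counts[sid] = col
                meta_rows[sid] = [ind, lv, dup]

    cm = CountMatrix(
        pd.DataFrame(counts, index=pd.Index(all_barcodes, name="barcode")),
        ValueKind.RAW_READS,
    )
    md = MetadataTable(
        pd.DataFrame.from_dict(
            meta_rows, orient="index", columns=["individual", "cell_type", "duplicate"]
        ).rename_axis("sample")
    )
    return SimTruth(clones, repeat_used, multi_clone), cm, md


def expected_repeat_use(L: int, cells_per_individual: list[int]) -> float:
    """Expected fraction of distinct barcodes detected in >=2 individuals.

    Barcodes are iid uniform draws from a library of size L. For small
    state spaces (L**total <= 2e6) the expectation of the ratio
    shared/distinct is computed by exhaustive enumeration; otherwise the
    ratio of expectations E[#shared]/E[#distinct] is returned via
    inclusion-exclusion (a good approximation once counts concentrate).
    """
    if L < 1:
        raise ValueError("library size must be >= 1")
    ns = [int(n) for n in cells_per_individual if n > 0]
    if len(ns) < 2:
        raise ValueError("need >=2 individuals with at least one cell")
    total = sum(ns)
    if L**total <= 2_000_000:
        acc = 0.0
        n_states = 0
        for assignment in product(range(L), repeat=total):
            sets, start = [], 0
            for n in ns:
                sets.append(set(assignment[start:start + n]))
                start += n
            seen: dict[int, int] = {}
            for s in sets:
                for b in s:
                    seen[b] = seen.get(b, 0) + 1
            distinct = len(seen)
            shared = sum(1 for v in seen.values() if v >= 2)
            acc += shared / distinct
            n_states += 1
        return acc / n_states
    p = [1.0 - (1.0 - 1.0 / L) ** n for n in ns]
    none = np.prod([1.0 - pi for pi in p])
    one = sum(pi * np.prod([1.0 - pj for j, pj in enumerate(p) if j != i])
              for i, pi in enumerate(p))
    e_detected = L * (1.0 - none)
    e_shared = L * (1.0 - none - one)
    return float(e_shared / e_detected)


def sample_repeat_use_frequency(
    L: int,
    cells_per_individual: list[int],
    n_reps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Monte-Carlo repeat-use frequencies under the generator's library model.

    Uses the same uniform-with-replacement draw as ``simulate_experiment``
    (vectorized over replicates); returns one shared/distinct fraction per
    replicate. Replicates where no barcode is detected yield NaN.
    """
    ns = [int(n) for n in cells_per_individual]
    freqs = np.empty(n_reps)
    for r in range(n_reps):
        draws = _draw_library_barcodes(rng, L, ns)
        presence = np.zeros((len(ns), L), dtype=bool)
        for i, d in enumerate(draws):
            presence[i, d] = True
        per_barcode = presence.sum(axis=0)
        distinct = int((per_barcode >= 1).sum())
        shared = int((per_barcode >= 2).sum())
        freqs[r] = shared / distinct if distinct else np.nan
    return freqs
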