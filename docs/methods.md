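# Methods

## The data model

The substrate of every analysis is a nonnegative barcode × sample matrix.
Its values may be raw sequencing reads, within-sample proportions
(normalized), proportions times a fixed factor (scaled), variance-
stabilized values (transformed), or cells per barcode per cell type from a
single-cell tally. The value kind is carried with the matrix and checked
by operations whose semantics depend on it (the arcsine transform, for
instance, refuses anything that is not on the proportion scale). A
metadata table maps each sample id to the values of the experimental
variables (individual, cell type, organ, timepoint, duplicate label);
sample ids that are underscore-joined variable values can be parsed
directly, but an explicit metadata file always takes precedence.

Readers retain all-zero barcodes and report them as warnings; only
analyses that mathematically require nonzero rows (row normalization,
clustering) drop them, again with a warning. Barcode ids are opaque
strings — sequence-level processing (extraction, error correction,
reference matching) is upstream of this package.

## Duplicate QC and merging

Each lysed sample is amplified and sequenced twice (duplicates A/B).
Three steps turn duplicate-level counts into one analysis-ready column per
sample:

1. **Correlation filter.** Pearson correlation between the two duplicates
   is computed on within-column proportions over the union of barcodes
   nonzero in at least one duplicate. Proportions make the filter
   insensitive to depth differences between the duplicate libraries;
   doubly-zero barcodes are excluded because (0, 0) pairs carry no
   information and only inflate the coefficient. Pairs with r ≤ 0.8
   (default) are flagged; they are dropped only on request, since a flag a
   scientist can inspect is safer than silent data loss. Spearman
   correlation (average ranks for ties, asymptotic p-values) is available
   for visualization-style summaries.
2. **Singleton zeroing.** A barcode with reads in exactly one of the two
   duplicates is treated as amplification noise and set to zero in both.
3. **Merge and renormalize.** Duplicates are summed (or averaged) and the
   merged columns renormalized to proportions.

Step 2 then 3 commute with normalization, and the whole procedure is
idempotent: merging a merged column with itself changes nothing.

## Repeat use

With a finite library of L barcodes, independent transductions can give
the same tag to founder cells in different individuals. A barcode counts
as detected in an individual if it is nonzero in at least one of that
individual's (merged) samples; the repeat-use frequency is

    |barcodes detected in ≥ 2 individuals| / |union of detected barcodes|.

The denominator convention is not forced by the biology; the union is the
default here (configurable via the building blocks) and is what the
bundled enumeration oracle computes. The sharing matrix (individuals ×
individuals, diagonal = per-individual richness) supports heatmap review.

## Diversity and clone sizes

Richness counts positive clones; Shannon H = −Σ p ln p is reported in
nats and Simpson as the Gini–Simpson index 1 − Σ p² (the conventions of
the vegan ecology package; inverse Simpson is available). Both evenness
metrics are computed on proportions and are therefore depth-invariant;
richness is not, and no rarefaction is applied — a documented caveat, not
a correction, because barcoding depths within an experiment are typically
comparable and rarefaction would add a stochastic step to a deterministic
pipeline.

Cumulative clone-size diagrams sort clones by descending abundance (ties
broken by barcode id for determinism) and plot the cumulative share of the
top k/n clones; a curve bowed far above the diagonal means few clones
dominate, the diagonal itself means equal contributions. `top_share`
reports the percentage held by the top k (or top q-fraction of) clones.

## Sharing and the lineage-bias classifier

Pairwise sharing tables take, per barcode, its mean within-sample
proportion in each of two levels of a variable (mean, not sum, so values
stay on the proportion scale for the arcsine display transform); barcodes
zero in both levels are excluded. Percentages of `only_a` / `only_b` /
`shared` barcodes are reported either pooled over individuals or as the
mean ± SD of per-individual percentages. Ternary tables row-normalize
three levels and keep the total for dot sizing.

The bias classifier works per individual. Reads are first column-
normalized (per-sample depth), replicate samples of one (individual,
lineage) cell are averaged, giving R_bc; rows are then normalized to give
P_bc, each barcode's distribution over the selected lineages. A barcode is
assigned every lineage with P_bc ≥ t **and** P_bc > 0. The strict
positivity clause is an interpretation choice: a bare "≥ t" rule would
assign every lineage to every barcode at t = 0, whereas with it t = 0
reduces exactly to presence/absence (uni- vs bi- vs multi-outcome
labeling). Consequences that double as test oracles: categories shrink
monotonically in t, and for t > 0.5 at most one lineage can qualify.
Barcodes with zero total across the selected lineages cannot be
row-normalized and are excluded. Category summaries report barcode counts
and, per lineage, the percentage of that lineage's classified abundance
contributed by each category, averaged over individuals — a partition of
100 % per lineage.

## Clustering and correlograms

Heatmap preparation column-normalizes, applies the arcsine transform by
default, drops all-zero rows, and clusters rows with Euclidean distance
and complete linkage through scipy's agglomerative implementation. Rows
are sorted by barcode id before linkage so the result is independent of
input order; column order follows the metadata unless column clustering is
requested (time courses are usually displayed in chronological, not
clustered, order). Correlograms compute, for every pair of levels,
Spearman (default) or Pearson correlation over the union of barcodes
nonzero in either level, with NaN (and a warning) where fewer than two
informative barcodes exist.

The arcsine-square-root transform is implemented as asin(√p) on
proportions — the standard variance-stabilizing choice for compositional
data; scaled matrices must be divided back to proportions first, and the
transform enforces that domain. The shifted log, log10(x + c) − log10(c),
maps zero to zero for any pseudocount c (default one read, or 1/depth on
the proportion scale).

## The simulator

The generator emulates the structure the analyses assume, with ground
truth for every quantity the pipeline estimates:

| parameter | default | meaning |
|---|---|---|
| `n_individuals` | 3 | transplanted mice / patients |
| `n_clones_per_individual` | 30 | founder clones per individual |
| `library_size` | 1000 | finite barcode pool (drives repeat use) |
| `lineages` | (cDC1, cDC2) | measured cell types |
| fate model | 30 % / 30 % / 40 % | uni-A / uni-B / bi-outcome priors |
| bi-outcome outputs | Dirichlet(2, 2) | unbalanced bi-outcome clones common |
| `clone_size_mu`, `clone_size_sigma` | 5.0, 1.0 | log-normal total output cells |
| `read_depth` | 100 000 | reads per duplicate per sample |
| `dropout` | 0.02 | per-duplicate detection failure |
| `overdispersion` | off | Dirichlet-multinomial PCR jackpotting |

Defaults were chosen once as a realistic mid-size barcoding experiment: a
three-digit library with tens of clones per individual yields a repeat-use
frequency of a few percent — the regime where the QC matters — and
log-normal clone sizes with σ = 1 give the heavy-tailed clone-size
distributions real experiments show. Sampling order is fixed (library
draws, fates, sizes, then reads per sample and duplicate) under a single
seeded generator, so one seed reproduces the experiment byte-for-byte.
`exact=True` replaces multinomial sampling with expected counts, giving a
noiseless limit in which QC + classification recover every clone's true
fate exactly — the identity the recovery tests assert.

`expected_repeat_use` is the independent oracle for the library model: for
tiny state spaces (L^total ≤ 2×10⁶) it enumerates every assignment of
cells to barcodes and averages the shared/distinct ratio exactly; beyond
that it returns the inclusion–exclusion ratio of expectations
E[#shared]/E[#detected], a documented approximation that concentrates as
counts grow.

What the generator does **not** emulate: sequencing-error barcode
families, index hopping, depth variation between samples, cell-type
misassignment in single-cell data, or clone dynamics over time. Passing
recovery tests therefore demonstrate correctness of the computations under
the stated sampling model, not robustness to those artefacts.

## Problem sizes and numerical choices

The test suite and the acceptance script run the generator at its default
scale (90 clones, 12 duplicate-level samples) and, for oracle comparisons,
at deliberately tiny scales: exhaustive clustering checks use ≤ 6 leaves
(100 random instances), repeat-use enumeration uses L ≤ 4 with ≤ 3 cells
per individual (10,000 Monte-Carlo draws compared within 3 standard
errors), and classifier recovery uses 100 replicates at depth 10⁴. These
sizes were chosen as the smallest at which the checked identities are
nontrivial.

Floats are written with 17 significant digits so written tables re-read to
within 1e-12; ties in abundance sorts and dendrogram input order are
broken by barcode id; correlation of a constant vector is NaN with a
warning rather than an error, mirroring how a scientist would triage a
degenerate duplicate.

## Known limitations

- No statistical hypothesis testing (group comparisons are left to
  dedicated tools); correlation coefficients are the only inferential
  quantities.
- Richness is sequencing-depth sensitive; compare it only across samples
  of comparable depth.
- The repeat-use frequency denominator is a convention; cross-study
  comparisons should check which convention was used.
- The classifier's per-individual P_bc requires each lineage to be
  measured in each individual; missing lineages simply contribute zero
  columns.
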