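# Methods

This note documents the models, conventions and numerical choices behind
`spnatlas`, and what the synthetic-data generators do and do not emulate.

## Quality control and retrograde-label order calling

Nuclei are retained when the mitochondrial count fraction is **strictly
below 0.05** and the detected-gene count is **strictly above 2,000**; both
boundaries follow the wording of the underlying protocol ("less than" /
"more than") and are configurable in `QCThresholds`.

A nucleus is XFP-positive when it carries **at least one** raw GFP or
mScarlet transcript count. Because ambient-RNA cleanup alters low counts,
the XFP signal must come from the raw (pre-cleanup) matrix; the pipeline
therefore carries raw XFP counts as per-nucleus metadata rather than
reading them from the filtered expression matrix. A cluster is classified
second-order (indirectly labeled) iff its XFP-positive fraction is
**strictly below the 10% cutoff**; a fraction of exactly 10% is
first-order. Overrides — clusters kept despite a sub-cutoff fraction, for
example when anatomical tracing independently confirms a direct
projection — are never automatic: they require an explicit cluster id plus
a justification string, and every application is logged. Dissection labels
can be pooled (e.g., rostral pons with the medulla as "hindbrain") by a
user-supplied mapping before fractions are computed; the pooling is a
config decision, not an inference.

With first-order rate ≥ 0.5, second-order rate ≤ 0.02 and ≥ 200 nuclei per
cluster, the binomial tails on either side of the 10% cutoff are below
10⁻⁶ per cluster, which is why the acceptance suite demands perfect
separation across 20 simulated atlases.

## Clustering workflow

The standard sequence is: per-nucleus library-size normalization to
**10,000 counts** (a fixed ecosystem convention; the total is arbitrary as
long as it is shared), `log1p`, selection of **2,000 variable genes** by
variance-stabilized dispersion, per-gene centering and unit scaling
(clipped at 10), PCA with **30 components** (full SVD — deterministic up
to component sign), a KNN graph (k = 15, Euclidean in PC space), and
community detection at **resolutions 0.5, 1, 2 and 3**. Community
detection is modularity optimization with a resolution parameter; the
default is Leiden (seeded and reproducible), with Louvain available since
the contract is the objective, not the optimizer. UMAP is computed only
for visualization and constellation node placement; no quantitative step
reads it except node centroids. A single pipeline seed fans out to the
per-stage seeds.

Doublet-like clusters are flagged when the mean detection fraction exceeds
a threshold (default 0.5) in **two or more mutually exclusive marker
programmes** (e.g., neuronal plus glial). The rule assumes the programmes
are on/off between the classes being separated; it is not sensitive to
shared, quantitatively shifted genes. Overlapping marker sets are
rejected.

## Taxonomy

Type centroids are arithmetic means of log-normalized expression over a
marker-gene panel; the panel size is data-dependent (it is the output of
marker calling, not a tunable parameter). The taxonomy tree is
**average-linkage agglomerative clustering on 1 − Pearson correlation**
between centroids — the common choice for transcriptomic dendrograms —
with metric and linkage pluggable. The companion-package tree-building
internals are not public; this choice is this package's own and is
validated against a brute-force O(n³) agglomeration oracle in the tests.
Type ids are assigned sequentially in dendrogram leaf order. Divisions
come from cutting the tree at its first splits (three by default); the
neurotransmitter-based fine-tuning of the modulatory division is a manual
curation step, represented as an explicit type → division override table.

### Module scores

The score of a gene set in a nucleus is the mean expression of the set
minus the mean expression of expression-matched controls: genes are ranked
by dataset-wide mean expression into **25 equal-occupancy bins**, and
**100 control genes per set gene** are sampled (without replacement,
seeded) from the non-set genes of the corresponding bin. Two degenerate
regimes are handled explicitly: when the set monopolizes its bin the
controls fall back to the nearest non-set genes by expression rank, and
when the set covers the whole gene universe the controls coincide with
the set and the score is exactly zero. An optional `control_pool`
restricts the universe, making the score provably invariant to genes
outside both set and pool. The implementation is cross-checked against
the scanpy `score_genes` routine as an independent oracle.

### LIM groups

Pontomedullary reticulospinal types are assigned to one of five groups
from the module scores of *Lmx1b* and the paralogous pairs
*Lhx2*/*Lhx9*, *Lhx3*/*Lhx4*, *Lhx1*/*Lhx5*: per type the group with the
highest median score wins; a type whose two leading medians are the
Lhx1/5 and Lhx3/4 pairs, both positive, with a ratio of at least **0.75**
(configurable) is assigned the combined Lhx1/5+Lhx3/4 group. The combined
rule is a heuristic — the source material states that the combined group
exists but gives no formula — and is flagged as such in the output. Types
with no positive median are left unassigned with a warning.

## Constellation graphs and heterogeneity

For each nucleus the **15 nearest neighbors** are found in the reduced
space, excluding the nucleus itself; distance ties are broken by stable
index order. "Reduced space" is the PC space used for clustering — UMAP is
treated as visualization only — but the functions accept any coordinate
matrix. Row *t* of the fraction matrix pools the neighbor slots of type
*t*'s nuclei and is normalized to sum to one (the diagonal self-fraction
is retained in the matrix but never drawn). An undirected edge exists iff
either directed fraction **strictly exceeds 5%** (the strict reading of
"more than 5%"); the width drawn at each endpoint is that endpoint's
fraction divided by the global maximum off-diagonal fraction, so the
strongest directed relationship spans 100% of its node's width. Node area
is proportional to log(nucleus count).

The heterogeneity score is the mean Euclidean distance to the 15 nearest
neighbors in a **100-dimensional** PC space, Z-standardized over nuclei
(mean 0, SD 1 by construction, asserted to 10⁻¹²). Degenerate data in
which every nucleus has the same mean neighbor distance raise an error
rather than returning an all-zero score.

## Cross-taxonomy mapping

The mapping gene set is the union of the top differentially expressed
genes per cluster comparison (default **50 per comparison** — a documented
choice, exposed in config, since no per-pair count is prescribed),
intersected with the genes present in both datasets. Each query cell goes
to the reference centroid with the highest Pearson correlation over that
set (Euclidean distance available); ties break to the lower centroid id
and are logged, and a query cell that is constant over the gene set falls
back to Euclidean assignment with a warning. Mapping is exact flat
nearest-centroid: approximate hierarchical search is an optimization, not
a semantic change, and is out of scope. Correspondence tables apply a
reciprocal support filter (clusters with fewer than **3** mapped cells
removed, both directions; idempotent), and confusion matrices are
aggregated up the reference hierarchy, conserving counts across levels.

## Differential expression and proportions

A gene is tested only if (a) it is detected in at least **25%** of the
nuclei of at least one group (matching the reference semantics of the
`min.pct` flag) and (b) the natural-log fold change between group means —
computed on library-normalized means with a pseudo-count of 1 — is at
least **0.25** in magnitude. The default statistic is a two-part hurdle:
a two-proportion z-test on detection plus a Wilcoxon rank-sum on the
positive expression values, combined by Stouffer's method with signed
components; either part is dropped when degenerate (no detection
variation, or too few positive values). A plain rank-sum over all values
is available in config. This is a deliberate divergence from the MAST
hurdle regression used in the source workflow: the two-part test captures
the same detection-plus-level structure without reimplementing the full
GLM, and its empirical type-I error on null negative-binomial simulations
is within 0.05 ± 0.01 (asserted in the acceptance suite at 2,000 genes ×
20 replicates, 200 + 200 nuclei). Benjamini–Hochberg correction runs over
the tested genes of each comparison separately; significance requires
adjusted p < 0.05.

Projection proportions per type tabulate the sort channel (GFP →
cervical, dual, mScarlet → lumbar); both the three-way split and the
pooled dual-or-lumbar fraction are emitted, since the pooling convention
can differ between displays. Section-series scaling multiplies per-region
counts by the number of series (default **4**, for one-of-four series
quantified) and reports percentages of the brain-wide scaled total.

## Electrophysiology

All ms/µs constants are converted to samples at the recording's own
sampling rate; 20 kHz is the default acquisition convention, not a
requirement.

* **Cell-attached detection.** Candidate spikes are local minima below
  `median − 5·σ̂`, where σ̂ is the normal-consistent MAD of the analysis
  segment (a robust noise-SD estimate that spikes cannot inflate), with a
  prominence requirement at the same depth so that noise minima riding on
  a spike trough do not count as separate candidates. A spike is kept
  only if no other candidate lies within ±5 ms (two spikes 3 ms apart are
  both rejected), and its ±5 ms window must lie inside the trace.
* **Waveform normalization.** Baseline is the mean of the first
  **3.75 ms** of the window; after subtraction each waveform is divided by
  the magnitude of its negative peak, making the minimum exactly −1, and
  the per-cell average is taken. Half-peak width is the time between the
  first downward and subsequent upward linear-interpolated crossings of
  the −0.5 line. Note that per-waveform normalization by a noisy peak
  slightly biases the averaged width downward at low SNR; this is a
  property of the estimator, visible in the acceptance report's
  half-width recovery.
* **AP features.** Threshold is the voltage at the last sample before the
  forward difference first reaches **12 V/s** (0.6 mV per 50 µs sample at
  20 kHz). Peak is the maximum after that sample; amplitude = peak −
  threshold; half width is measured at threshold + amplitude/2 with
  linear interpolation and reported in µs; fAHP is **threshold − trough**
  over the 4 ms after the peak, positive when the trough is below
  threshold (the sign convention is this package's, documented because
  only a "difference" is prescribed).
* **Passive and F–I.** Input resistance is the OLS slope of steady-state
  deflection (mV) against injected current (pA), × 1000 → MΩ. F–I counts
  APs per 1 s step (0–1000 pA in 50 pA increments) using the same dV/dt
  criterion with a **2 ms refractory separation** (an unprescribed,
  logged constant); missing steps are recorded as absent, not zero. Group
  comparisons use the two-sided Mann–Whitney U test, exact for small
  untied samples.

## Imaging

Background subtraction is morphological top-hat with a disk structuring
element (default radius **15 px**, configurable; no radius is
prescribed). Binarization keeps pixels **strictly above 120** (8-bit
units), then removes connected components of two pixels or fewer —
**8-connectivity** by default (diagonals count, the common convention),
switchable to 4. Density grids count retained pixels in 20 × 20 px bins
after zero-padding to a bin multiple, so the bin totals conserve the
retained pixel count exactly. "Smoothing with 100 × 100 bins" is
ambiguous between pixels and bins; the default reads it as a 100 × 100 px
(5 × 5 bin) normalized moving average with reflective edge padding
(mass-preserving in the interior), and the bin-unit reading is selectable.
Contours are iso-levels of the smoothed grid, evenly spaced strictly
between zero and the maximum, exported in image coordinates.

Colocalization: a pixel is co-intense when both channels strictly exceed
their per-channel thresholds — Otsu per channel by default, fixed cutoffs
overridable, since "high co-occurrent intensity" is not quantified — and a
mask is positive when **at least 65%** of its pixels are co-intense
(boundary inclusive). Soma area is the mask pixel count times the pixel
area.

## Synthetic data: what it emulates and what it does not

The count generator draws negative-binomial (gamma–Poisson) counts with
lognormal gene abundances, a shared dispersion (default 10), lognormal
library sizes (mean 10,000), a 13-gene `mt-` block pinned to a target
mitochondrial fraction (default 0.02), and per-type disjoint marker
blocks up-regulated by `exp(marker_logfc)` (default natural-log FC 1).
The default atlas is 12 types × 300 nuclei × 2,000 genes. XFP counts are
zero-inflated Poisson with Bernoulli rate 0.8 for first-order and 0.02
for second-order types (default 25% of types second-order); sort channels
follow per-type Dirichlet-distributed cervical/dual/lumbar compositions.
Not emulated: ambient RNA, doublet chemistry, batch effects, spatial
structure, platform differences, or realistic gene–gene correlation —
passing tests demonstrate algorithmic correctness on the declared
generative model, not robustness to those artifacts.

The ephys generator inserts a difference-of-exponentials negative
transient whose sampled full width at half peak is calibrated to the
requested value, at Poisson times thinned to a 12 ms minimum separation
(and refuses rates ≥ 100 Hz, where ±5 ms isolation is impossible).
Whole-cell sweeps are a leaky integrate-and-fire cell (τ = 20 ms, rest
−65 mV, threshold −45 mV) with a stereotyped piecewise-linear AP and an
analytic expected spike count used as the test oracle. Real recordings'
channel noise spectra, adaptation and bursting are not modeled.

The image generator places non-overlapping constant-intensity disks over
folded-normal background noise clipped at 3 SD (so background never
reaches the 120 threshold at default settings), and in two-channel mode
makes a Bernoulli-`coloc_fraction_true` subset of masks bright in both
channels. Real axonal morphology (thin neurites, partial-volume
intensities) is not modeled; the generator provides exact planted truth
for the thresholding, conservation and colocalization rules.

## Problem sizes in tests

The test and acceptance runs use the default 3,600-nucleus atlas for
clustering recovery, 20 fresh 500-gene atlases for the order-calling
sweep, 2,000 genes × 20 replicates for the DE calibration, and brute-force
oracles at 60–200 points; these sizes make every check exact or
statistically decisive while the full suite completes in a couple of
minutes.

## Known limitations

* The DE test is a hurdle approximation, not MAST; borderline genes can
  differ from a MAST-based analysis.
* The combined LIM-group rule is a documented heuristic.
* Duplicate-type merging across bordering dissections and type naming are
  curation steps represented by explicit override/decision tables, not
  inferred.
* UMAP coordinates are seed-deterministic but solver-version dependent;
  only node placement consumes them.
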