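# Methods

This note documents the models, conventions and parameter choices behind
`coexnet`, the places where the design was genuinely open, and what the
synthetic benchmarks do and do not demonstrate.

## Normalisation and expression filtering

Counts per million are computed against the plain column sum of the input
matrix — no compositional scaling factors (TMM and relatives) are applied,
since hard-threshold rank-correlation networks are insensitive to smooth
per-sample scaling.  The expression filter keeps a gene only when
`cpm > min_cpm` (default 5) **strictly** in **every** sample; a gene sitting
exactly on the floor is removed.  The filter is idempotent, monotone in the
floor, and order-preserving.  When outlier samples are removed during QC,
library sizes and the filter are recomputed on the surviving samples by
default (`recompute_cpm_after_qc`), because a library built from an aberrant
sample should not constrain the post-QC gene universe; the flag exists
because the opposite convention is also found in practice.

## Outlier QC

Samples are compared within their treatment group by the quantitative
Jaccard (Ružička) distance on cpm profiles,
`d = 1 − Σ min/Σ max`, which equals `2B/(1+B)` for Bray–Curtis `B` — the
default quantitative convention of the vegan ecosystem.  A binarised
presence/absence mode is available but not default: with sequencing-depth
libraries nearly every gene is "present", so the binary distance carries
little signal.  Clustering is agglomerative with **complete linkage**
(average linkage available); complete linkage makes the merge height of a
cluster its diameter, so a fixed cut height (default 0.4) reads directly as
"no sample may be farther than 0.4 from its cluster".  The outlier rule —
flag everything outside the largest cluster at the cut — generalises the
one-boxed-singleton case; a tie for the largest cluster raises rather than
guessing, since the choice then genuinely needs inspection.

The leading log-fold-change MDS uses the top 500 per-pair gene differences
of `log₂(cpm + 2)` (prior count 2), the published defaults of the
limma/edgeR MDS procedure, followed by classical Torgerson MDS
(double-centering + eigendecomposition).  Axes are ordered by eigenvalue
and sign-fixed deterministically; embeddings are unique only up to
rotation/reflection, so tests compare pairwise embedding distances, not raw
coordinates.

## Association

Spearman rank correlation with mid-ranks for ties, computed as the Pearson
correlation of rank-transformed rows.  Rank correlation is invariant to
strictly monotone per-gene transforms, so correlating cpm or log-cpm is
equivalent (a `log_transform` flag exists for parity with other pipelines).
Genes constant across samples have undefined rank correlation and are
dropped with a warning.  The full gene × gene matrix is materialised
(float64; ~1.2 GB at 12k genes), which is acceptable on analysis
workstations; a blocked mode is deliberately out of scope.

## Network model and threshold selection

Hard thresholding keeps pairs with `|ρ| ≥ t` (absolute value by default —
strong negative co-expression is as informative as positive; a
sign-restricted mode exists).  Metrics per threshold:

- **Degree fit (R², slope):** OLS of `log₁₀ n(k)` on `log₁₀ k` over the
  raw degree histogram (degrees ≥ 1 present in the network).  Fitting raw
  frequencies rather than the complementary CDF matches the
  "slope/power + R²" single-line reporting convention of the refinement
  table; it is the main fidelity risk of this module, since CDF-based fits
  are statistically better behaved.
- **meanCC:** mean local clustering coefficient over used vertices
  (degree-0 vertices are outside the network model; degree-1 vertices
  contribute 0).
- **meanPath:** mean shortest-path length over connected pairs within the
  largest component only.  Whole-graph averaging is impossible with any
  disconnected pair, and reported %bigComp values near 99 % make the
  largest-component convention the only consistent reading.
- **%used** = used vertices / gene universe; **%bigComp** = largest
  component / used vertices.  The %bigComp denominator was an open choice;
  used-vertices reproduces the observed ≥ 99 % pattern.

Default grid: {0.845, 0.85, 0.855, 0.858, 0.86, 0.862} — the refinement
range between a "best" and an "alternative" threshold proposal.  Selection:
among rows passing all five criteria (R² > 0.9, meanCC < 0.5, meanPath < 5,
%used > 95, %bigComp > 95) take the maximal R², ties toward the larger
threshold; when nothing passes everything, the row satisfying the most
criteria wins (ties: higher R², then larger threshold) and the result is
flagged *relaxed* rather than silently promoted.  All five bounds are
configurable, which also lets a user encode a different operating point
(e.g. tightening %used can force the selector onto a specific
intermediate-threshold row).

Degenerate metrics (empty network, single degree class, single-vertex
component) are reported as NaN sentinels per row; the sweep never aborts on
a degenerate threshold.

## Vicinity networks

A VN is the induced subgraph on a seed gene plus its direct neighbours
(radius 1; configurable).  Statistics follow the NetworkAnalyzer
conventions: average number of neighbors `2E/N` and simple-graph density
`2E/(N(N−1)) = mean degree/(N−1)`.  The retention filter keeps VNs with the
chosen statistic strictly above a bound (default: density > 0.5).  The
metric is configurable between density and mean clustering because
published VN reports mix the two conventions; both are always reported for
every VN regardless of which gates retention.  Exports are GraphML (node
attributes `is_seed`, `degree`; edge attribute `weight` = ρ) plus TSV
mirrors and a group-blocked long-format expression-profile table.

## Synthetic data generator

The generator emulates the statistical shape of a two-tissue RNA-seq panel:

- **Counts:** negative binomial with size (shape) parameter `dispersion`
  (default 10, i.e. squared biological CV 0.1 — field-collected biological
  replicates), means `μ_g` log-uniform over `base_mean_log_range`
  (default ln 20 … ln 400 counts).
- **Modules:** each of a handful of modules (default four, sizes 36/12/10/34
  — the scale of interpretable vicinity networks) shares one latent
  log-expression factor per sample: gene g in module m has mean
  `μ_g · exp(strength · f_ms)` with `f_ms = latent_sd·z_ms + o_ms`,
  `z ~ N(0,1)`.  `latent_sd = 0.6` was calibrated once so that the
  conventional coupling `strength = 2` yields within-module Spearman ≈ 0.93
  — comfortably above the 0.845–0.862 operating grid while keeping
  expression swings within ~e^±2.4, i.e. inside the expressed regime.
  Module genes draw their base means from the upper half of the range:
  the modules of interest sit among robustly expressed genes, and planting
  them at the filter boundary would conflate the expression filter with
  network recovery.
- **Groups:** module factors carry a per-group offset
  (`± latent_sd · group_effect/2`, sign alternating across modules), giving
  module genes a between-group fold change; background genes have no group
  effect.  This reproduces group separation in the leading-logFC MDS in
  most replicates; because group and replicate variation act through the
  same latent factor, occasional single-replicate overlap on dim 1 is
  expected and real.
- **Outliers:** aberrant samples multiply every gene's mean by independent
  log-normal factors of log-scale `outlier_shift` (default 2).
  `inject_outlier` applies the same corruption to an existing matrix,
  treating observed counts as plug-in means and redrawing Poisson.

Everything is bit-reproducible from `rng_seed`.

**What the generator does not model:** gene-length and GC biases,
compositional library effects beyond what normalisation removes, correlated
module–module structure, heavy-tailed expression outliers within healthy
samples, and batch effects.  Recovery results on this generator therefore
demonstrate the *machinery* (filter → correlation → threshold → VN chain
behaves correctly when modules exist at the assumed correlation scale), not
performance on arbitrary real data.

The outlier-power benchmark uses a module-free replicate group: the module
latent factors model between-tissue expression contrast, and biological
replicates of a single tissue do not swing e^±2.4 in concert — with modules
planted, replicate groups occasionally look heterogeneous enough to flag a
healthy sample, which misrepresents the replicate-homogeneity scenario the
QC step addresses.

## Benchmark problem sizes

The validation studies run at reduced scale chosen to exercise every code
path with comfortable statistical margins: module recovery uses 1,500 genes
(3 × 20-gene modules, 17 samples, 10 replicates), outlier power uses the
full 12,000-gene default over 6 replicates, the oracle-equivalence study
uses 100 random graphs of ≤ 60 nodes against triangle-enumeration,
Floyd–Warshall, union-find and closed-form OLS oracles (tolerance 1e-10),
and scale-free discrimination compares 200-node preferential-attachment
graphs with degree-matched Erdős–Rényi graphs over 20 replicates.  With
17 samples the null Spearman tail is thin (P(|ρ̂| ≥ 0.845) ≈ 1e-5), so
background false edges are rare at these gene counts; with ~11 samples the
same thresholds admit a visible noise component — sample size, not gene
count, is what the grid presumes.

## Numerical conventions

- Ties in the largest-component choice break toward the component
  containing the smallest vertex label (deterministic outputs).
- A two-point degree histogram fits a line exactly: R² is defined as 1
  when the residual sum of squares vanishes even if the total sum of
  squares is 0.
- Correlations are clipped to [−1, 1] and the diagonal forced to 1 to
  absorb floating-point drift; the matrix is symmetrised.
- TSV outputs use `%.6g` floats; manifests record SHA-256 digests so reruns
  are verifiable byte for byte.

## Known limitations

- The degree-fit-on-raw-frequencies convention (above) can reward networks
  whose histograms merely *look* linear on few points; two-point histograms
  trivially achieve R² = 1.
- Hard thresholding discards edge-weight information below the cut; no
  soft-thresholding (WGCNA-style) mode is provided.
- P-values for correlations, batch correction, and statistical tests of
  group separation are out of scope.
- The selection criteria can be mutually unsatisfiable on sparse or small
  data; the relaxed flag makes this explicit instead of failing, and
  downstream consumers should check it.
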