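# Methods

This note documents the models, algorithms and numerical choices behind
`modpres`, what the synthetic generator does and does not emulate, and the
package's known limitations.

## Synthetic study generator

Each planted module is driven by one latent factor per condition.  Gene *g*
of module *m* in condition *c*, sample *s*:

    x_gs = b_g + δ_batch(s) · (λ_gmc · f_cs + ε_gs) + γ_batch(s) + covariate terms

with `f ~ N(0,1)` per sample, `ε ~ N(0, σ²)`, and a per-gene baseline
`b_g ~ U(6, 12)` on the log2-intensity scale shared by all conditions.
Background genes have λ = 0.  Defaults: λ = 0.8, σ = 0.6, giving unit gene
variance and within-module correlation λ²/(λ²+σ²) = 0.64.

**Regimes.**  Per test condition a module is `preserved` (same λ),
`weakened` (reduced λ, default half), `split` (two independent factors on the
module halves) or `destroyed` (λ = 0).  `destroyed` and λ = 0 imply each
other by construction.

**Hub structure.**  With `min_loading_fraction < 1` the per-gene loadings
decay geometrically from λ to λ·fraction across the module, making the
leading genes hubs.  This matters twice: (i) a constant-loading module gives
every member the same expected connectivity, so the network's degree
distribution is a set of spikes and *cannot* fit scale-free topology at any
soft power (the fit saturates around 0.55); (ii) without a within-module
connectivity pattern there is nothing for the connectivity-preservation
statistics to preserve.  Geometric decay to 10% (used by the modular
benchmark, `modular_study_config`) produces heavy-tailed connectivities and
scan fits of 0.91–0.97 at β ≈ 9–12; decay to 60% (the pipeline demo) keeps
module boundaries sharp enough for exact recovery while still giving the
leading genes the highest intramodular connectivity.  The default is 1.0
(the plain factor model), for which the closed-form correlation structure
above holds exactly.

**Batch and covariate effects.**  Batch effects act on the centred
expression component: multiplication by a scale factor and addition of a
location shift, optionally with gene-specific variation around the shift
(`gene_shift_sd`) — real microarray batch effects are probe-specific, and
gene-level variation is also what the empirical-Bayes correction model
assumes.  Age is uniform on a configurable range (default 60–90 years) with
a per-gene slope on a designated gene subset; sex is Bernoulli(0.5) with an
additive shift on a second subset.

**Seeding.**  A single integer seed spawns one deterministic substream per
condition plus one for the baselines, so a condition simulated standalone is
bitwise identical to the same condition inside a study, and different seeds
change noise realizations but never the planted structure.

**What the generator does not emulate:** probe-level artefacts
(cross-hybridization, spatial effects), count-based RNA-seq noise,
non-Gaussian expression marginals, correlated module eigengenes, and
overlapping module membership.  Passing tests therefore demonstrate
correctness of the statistics under a Gaussian factor model, not robustness
to every property of real microarray data.

## Preprocessing

Stages run in a fixed order: probe summarization → abundance filter →
normalization → batch correction → covariate adjustment → outlier removal.
The driver refuses datasets whose batches span conditions, because batch
correction does not protect condition labels; within the pipeline each
condition is preprocessed independently, so batches never span conditions.

* **Probe summarization** averages the probes mapping to a gene; unmapped
  probes are dropped with a logged count.
* **Abundance filter** removes genes whose mean is *strictly below* the 5th
  percentile (linear interpolation between order statistics) of gene means;
  with tied means nothing is removed, and percentile 0 is the identity.
* **Normalization** applies log2 where needed, then shifts each sample so
  its median equals the global median of sample medians.  This replaces
  variance-stabilizing normalization: the network statistics under test
  operate on correlations, which the median alignment leaves untouched, and
  the generator produces log-scale data directly.
* **Batch correction** is the parametric empirical-Bayes location/scale
  model without covariate protection: per-gene standardization against the
  batch-size-weighted grand mean and pooled variance; per-batch per-gene
  moment estimates γ̂, δ̂²; normal prior on γ and inverse-gamma prior on δ²
  fitted across genes by the method of moments; the coupled posterior
  estimates solved by fixed-point iteration (tolerance 1e-4); adjusted
  values back-transformed.  A single batch returns the input with an
  identity model; a batch of one sample is an error.  The implementation is
  cross-checked in the test suite against scanpy's independent ComBat port.
  Note the correction is only *approximately* idempotent: shrinkage leaves
  small per-gene batch residuals that a second pass re-estimates (measured:
  second-pass mean cell change ≈ 1% of the first pass).
* **Covariate adjustment** is per-gene OLS on the centred covariates; the
  fitted covariate contribution is subtracted so gene means are preserved to
  machine precision.  Constant covariates are dropped with a warning;
  collinear sets are an error.  No shrinkage is applied by design — the
  amount of shrinkage used by empirical-Bayes variants is a free parameter
  we have no basis to set, and at the pipeline's sample sizes OLS residual
  confounding is already below the tested tolerances.
* **Outlier removal** standardizes each sample's mean correlation with all
  other samples and removes samples below z = −2.5 (a deterministic stand-in
  for visual dendrogram inspection); the average-linkage sample tree is
  returned for plotting.  Zero variance of the mean correlations means no
  outliers.

## Network construction

Signed adjacency `a_ij = ((1+r)/2)^β` maps anticorrelation to 0; raising raw
correlations to an integer power is not sign-safe for even β, which is why
the signed transform is the only one offered.  The scale-free fit bins the
connectivities `k_i = Σ_{j≠i} a_ij` into 10 equal-width bins, drops empty
bins, regresses log10(bin frequency) on log10(mean k), and signs R² by
−sign(slope) so only decreasing frequency–connectivity relationships count.
`select_soft_threshold` picks the smallest β in the grid (default 1..20)
reaching the target fit (default 0.90), falling back to the arg-max with a
flag when the target is unreachable (e.g. pure noise).  Degenerate degree
distributions (all k equal, or fewer than 3 usable bins) are errors at the
single-β level and skipped as NaN inside the scan.

TOM follows the standard formula
`TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 − a_ij)`, and 1 − TOM
is the clustering dissimilarity (direct 1 − adjacency clustering is
available by passing a custom dissimilarity to `detect_modules`).

## Module detection

Average-linkage agglomeration (scipy) of the TOM dissimilarity, then a
deterministic tree-variant dynamic cut.  A branch becomes a module iff

1. it has ≥ `min_module_size` leaves (default 30),
2. its own merge completes below the `cut_height_quantile` quantile of merge
   heights (default 0.99), and
3. it is *separated*: the gap between its parent merge height and its own is
   at least `min_gap_fraction` (default 0.05) of the tree's total height
   range.

Minimal qualifying branches win (an accepted branch blocks its ancestors).
The separation rule is what distinguishes this cut from a flat one: tightly
coexpressed blocks attach to the rest of the tree far above their internal
merges, while branches of unstructured genes merge onward almost
immediately — a flat cut at any height quantile would emit large spurious
clusters on pure noise and, conversely, can fail to isolate real modules
whose attachment heights sit below the cut.  No PAM-style reassignment stage
is applied, so modules with very diffuse boundaries (strong hub decay) are
detected as their cores with tail genes left grey; there is no
eigengene-similarity merging either.  Modules are named by decreasing size
along the conventional colour sequence (`turquoise`, `blue`, `brown`, …);
unassigned genes are `grey`.

Eigengenes are the first right singular vectors of the standardized module
submatrices (unit norm, oriented to correlate non-negatively with the module
mean profile), with the explained-variance proportion from the squared
singular values.  kME is the gene–eigengene Pearson correlation with
two-sided p-values from the t transform at n−2 df; kIM is the within-module
adjacency sum; hubs are the top-10 members by kIM among genes with own-module
kME p < 0.05.  The dataset–module QC correlates each eigengene with each
cohort's one-vs-rest indicator and applies Benjamini–Hochberg adjustment
across the table.

## Preservation statistics

For reference module *q* with gene index set M in test network T (reference
network R, both on one shared, identically ordered gene universe):

* density: `meanAdj` = mean off-diagonal T-adjacency within M;
  `propVarExplained` = variance explained by M's eigengene computed in the
  test data; `meanSignAwareKME` = mean over M of sign(kME_R)·kME_T, each kME
  taken to the module's own eigengene on its side;
* connectivity: `cor.kIM` = Pearson correlation over M of reference vs test
  intramodular connectivity; `cor.kME` = correlation over *all* genes of
  reference vs test kME to this module; `cor.cor` = correlation of the
  vectorized upper triangles of the within-module correlation matrices.

The permutation null draws, for each module size, a uniform random gene set
of that size from the test universe (the label-permutation scheme) and
recomputes all six statistics on both sides; defaults are 500 permutations.
Per statistic, `Z = (observed − null mean)/null SD` and the permutation p
uses the add-one estimator `(1 + #{perm ≥ obs})/(n_perm + 1)`, so p is never
zero.  A statistic whose null SD is zero is dropped from its class median
with a warning instead of producing an infinite Z.  `Z_density` and
`Z_connectivity` are the class medians; `Z_summary` is their mean;
`Z_summary > 10` flags a module as well-preserved.  This statistic set is a
deliberately minimal 3+3 selection with the standard aggregation
(median within class, mean across classes); separability statistics and
medianRank are out of scope, and preservation is directional — reference
modules in the test network only.

Two calibration facts, both exercised by the test suite, are worth knowing
when reading Z values:

* Z magnitudes grow with the universe size.  When a module is a large
  fraction of the gene universe, the permutation draws inherit much of its
  signal and Z_summary saturates; at a 10% module share the well-preservation
  rule behaves as intended.
* Z_summary decreases monotonically across preserved → weakened → destroyed
  regimes in studies with several modules, where the permutation-null width
  is set by the network as a whole; with a single planted module the null
  narrows as the module weakens and can mask the decrease.

Cross-tabulation counts shared genes for every reference/test module pair
(grey included) and computes upper-tail hypergeometric (Fisher exact)
p-values entirely in log space: log-gamma pmf terms combined by logsumexp,
reported as −log10 p.  This keeps overlaps whose p underflows double
precision (≈10⁻³¹⁰ and far beyond) finite and comparable.

`ΔZ_summary = Z_summary(A) − Z_summary(B)` per module, with calls GOP
(positive), LOP (negative) and neutral (exactly zero).  The table is
antisymmetric under swapping A and B by construction.

## Pipeline and reproducibility

`run_pipeline` executes load → preprocess (per condition) → gene-universe
harmonization (intersection in reference order) → network → module detection
→ cross-tabulation → preservation → differential → report.  Exactly two test
conditions enable the differential stage; one test condition runs with a
warning and no ΔZ table.  A single seed in the configuration derives
per-stage sub-seeds deterministically; all outputs are TSV with fixed
formatting (`NA` for missing), and the report is rendered *from* the saved
TSVs, so regenerating it from a run directory reproduces the original byte
for byte, and two runs with the same configuration and seed are
byte-identical.

## Problem sizes used by the validation suite

The test-bench study conditions were chosen once as desk-scale realizations
of the statistics' operating regime: the modular soft-threshold benchmark
uses 10 hub-structured 50-gene modules in 1000 genes × 100 samples; the
well-preservation scenario one 100-gene module (λ = 0.9) in 1000 genes × 60
samples with 200 permutations; the regime-monotonicity scenario one focal
80-gene module plus four background modules in 800 genes × 60 samples, 100
permutations, 25 replicates; null calibration a 600-gene structureless study
scored over twenty 30-gene pseudo-modules at 200 permutations.

## Known limitations

* Desk scale by contract: dense gene × gene matrices bound practical use to
  roughly ≤ 5000 genes; no block-wise approximation is provided.
* The dynamic cut's tree variant has no reassignment stage, so diffuse
  module boundaries shrink to cores (see above).
* The preservation statistic set is minimal; absolute Z_summary magnitudes
  are not comparable to runs of other implementations with larger statistic
  sets, although the definition, calibration and the ΔZ arithmetic are.
* Batch correction assumes the location/scale model and at least two samples
  per batch; it does not protect biological covariates and must not be run
  across conditions.
* The permutation p-values are add-one estimates bounded below by
  1/(n_perm+1); inference at finer resolution needs more permutations.
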