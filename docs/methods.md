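# Methods

## Study design being emulated

The pipeline reproduces the statistical skeleton of an imaging-
transcriptomics study: a cohort of adolescents (n = 248, 14–25 years)
with a two-timepoint questionnaire trait and a 68-region cortical MT
matrix; a regions×genes expression atlas; annotation lists from case-
control differential-expression (DE) studies; and a protein-interaction
edge list. Because the package must run anywhere without data access,
all inputs are generated by `srmtx.synthetic` with known ground truth,
and every claim the test suite makes is a claim about recovering that
ground truth — not about any real cohort.

## The trait

Endorsement rates are modelled as a latent Beta(1.42618, 4.77461)
variable — shape parameters frozen from a one-time fit so the population
mean is 0.23 and the median 0.20, the skew characteristic of
psychometric endorsement data in non-clinical samples. The two
assessments are latent ± a symmetric, range-respecting perturbation
(s.d. 0.03 on the unit interval), so their mean equals the latent trait
exactly; the analysis uses that mean, √-transformed to tame the skew.
Missing single assessments fall back to the observed one; subjects
missing both are dropped with a log entry.

## Regional MT and the planted trait effect

MT (in saturation units of magnitude ~1) follows

    MT[i, j] = a_j + b_j (age_i − 14) + β_j √T_i + ε_ij,   ε ~ N(0, 0.05²)

with spatially smooth intercept (`a`, mean 1.0, s.d. 0.06) and slope
(`b`, mean 0.010/yr, s.d. 0.005) fields. Age is centered at exactly 14
years so the intercept is "MT at 14". Smooth fields are Gaussian
processes with a squared-exponential kernel over **chordal** distance on
the unit sphere (length scale 0.5 rad); the chordal form is used because
it is positive definite on the sphere (restriction of the R³ kernel),
whereas the squared exponential of great-circle distance is not, and the
two metrics are nearly identical at this length scale.

β_j is set from the target residual correlation r_j by
β = r·σ_ε / (σ_√T √(1 − r²)), using the sample s.d. of √T, so the
age-residualized MT–trait correlation matches its target in
expectation. Targets are r = .3 in the four planted regions; the other
regions carry a smooth zero-mean background field of amplitude 0.08 (r
units, clipped to ±0.9·r_peak). The background reflects that cortical
trait–effect maps are spatially continuous — "significant" regions are
the peaks of a smooth field, not spikes in a sea of exact zeros. This
matters downstream: with a 4-spike/zeros map, all association
information lives in 4 of 68 regions, so bootstrap resampling of
regions caps every gene's |Z| near 2 and no gene can pass genome-wide
FDR at these effect sizes; with the continuous map the association is
distributed and gene recovery behaves like the real analyses it
emulates. Replicate-style calibration experiments (type-I error,
region-recovery sensitivity/FDP) use the spiky form (background 0), the
cleaner null.

## Expression and annotations

The transcriptome is scaled to 2,000 genes (10% planted, half loading
+1 and half −1 on the standardized true trait–effect map, plus smooth
spatial noise of s.d. 1.0 and per-gene baselines ~N(5, 1)); the full
20k-gene genome is statistically redundant for every property tested
and this size keeps a complete study under 15 s. Genes are z-scored
across regions before PLS (zero-variance genes dropped); z-scoring is
exposed as a switch since raw-scale PLS is also defensible.

Annotation lists (100 genes each) are drawn by weighted sampling
without replacement at odds 8 for the favored planted class —
"downregulated-like" favors planted-positive genes, "upregulated-like"
planted-negative, with cell-type-like lists mirroring the same
asymmetry and two unenriched controls. DE tables assign
logFC = −loading + N(0, 1), so planted-positive genes look
transcriptionally downregulated, giving the negative weight–DE
correlation the enrichment asymmetry implies. The PPI edge list is
Erdős–Rényi at density 0.005 over the gene universe plus a density-0.5
module on 20 genes planted inside (positive ∩ downregulated-like), the
set the network stage targets.

Probe-level construction (`srmtx.expression`) collapses multi-probe
genes to the probe with the highest mean expression across samples
(ties to the lexicographically smallest probe id, for determinism) and
averages samples within donor-and-region before averaging across
donors, so donors with more samples cannot dominate a region. Regions
with no samples are a hard error by default; nearest-centroid borrowing
is deliberately not silently applied.

## Estimators and inference

* **Normality gate**: Lilliefors-style KS test (normal, estimated
  mean/s.d.) on both variables at α = .05; Spearman if either rejects.
  Applied to both the trait and the residuals since the gate's target is
  ambiguous in practice; a `robust` flag forces Spearman throughout.
  With two Gaussian inputs the gate selects Pearson with probability
  ≈ 0.95² ≈ 0.90.
* **FDR**: Benjamini–Hochberg at q < .05, one family per regional map
  and one per gene-weight table; cell-type enrichment is corrected
  within each target list's family; DE-list overlaps are reported as
  raw permutation p; disorder-level weight–DE correlations are
  Bonferroni-adjusted. Regions with fewer than 8 complete pairs are
  flagged and excluded from the family.
* **PLS1**: NIPALS component 1; for a univariate response the weight
  vector is exactly the normalized cross-covariance Xᵀy (the NIPALS
  fixed point), computed directly and cross-checked against
  scikit-learn's `PLSRegression` in the tests. Variance explained is
  the squared Pearson correlation of the region scores with the map.
* **Spin null**: uniform SO(3) rotations (scipy's Haar sampler), the
  sagittal mirror image applied to the right hemisphere; original and
  rotated centroids are matched one-to-one greedily in order of
  increasing arc distance, per hemisphere, so every null is a true
  permutation that never mixes hemispheres. The map (not the expression
  matrix) is permuted; p = (1 + #{null ≥ observed}) / (n_perm + 1).
  Defaults: 1,000 spins.
* **Bootstrap gene weights**: regions resampled with replacement
  (constant-map resamples redrawn and logged), component recomputed on
  the re-centered resample, sign-aligned to the original. Replicates
  share the original component's scale — each raw cross-covariance
  vector is divided by the *original* norm, not re-normalized — because
  per-replicate normalization lets the replicate norm's noise enter
  every gene's s.e. and inflates Z by ~√2 under a global null; with the
  fixed scale the measured null p < .05 rate is 0.053 at the 68-region
  geometry. p-values use the normal reference (a t with n−2 df is
  marginally better at small region counts; immaterial at 68). Genes
  with zero bootstrap s.e. get p = 1 and are logged. Defaults: 1,000
  resamples.
* **Enrichment null**: size-matched random subsets of the universe
  (genes entering the PLS), without replacement; converges to the
  hypergeometric upper tail, which the tests assert at n_perm = 10,000.
  Gene matching is exact-symbol and case-sensitive.
* **PPI null**: random node sets matched on mapped size only, drawn
  from the graph universe; a degree-decile-matched variant is available
  by flag. Graphs are simplified on load. Genes absent from the
  universe are dropped *before* size matching so the null is not
  deflated. Connected components are reported descriptively only.

## Reproducibility

One top-level seed drives everything: `numpy.random.SeedSequence`
spawn keys give each artifact and each stochastic stage its own
independent stream, so regenerating one input never perturbs another,
and two runs with the same config are byte-identical (asserted in the
suite). All sub-seeds stay below 2³¹.

## Problem sizes

Defaults were chosen once as the package's study conditions: cohort
248×68 (the geometry of the motivating design), 2,000 genes, 1,000
spins/bootstraps, 10,000 enrichment and PPI permutations. Calibration
experiments in the test suite use 100–1,000 replicates at these or
smaller geometries. A complete study runs in ~15 s on one CPU; the full
test suite in ~2 minutes.

## What passing tests do and do not show

The generator emulates the *statistical structure* of the real inputs —
skewed traits, age trends, spatially autocorrelated maps and expression,
enriched annotations, a dense interaction module — but not donor-level
atlas structure, questionnaire item psychometrics, site/scanner effects
beyond labels, or realistic PPI degree distributions. Recovery of
planted structure therefore validates the estimators and their error
control under the stated model, not the biological conclusions of any
particular cohort. Known limitations: gene-level bootstrap inference is
conditional on the observed map and does not protect against chance
spatial alignment of smooth fields (that is the spin test's job, at the
component level); the background effect field means region-level
"false" positives at default conditions are usually genuine small
effects; and the KS gate's estimated-parameter correction is the table
approximation implemented in statsmodels.
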