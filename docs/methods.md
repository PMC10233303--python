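# Methods

## Synthetic cohort model

The generator produces the inputs of a two-region, multi-batch TMT
cohort on the log2 scale:

```
log2 x[p, s] = baseline[p]
             + loading[p] · L[module(p), case(s), region(s)]
             + batch_offset[p, batch(s)]
             + Σ_c slope[p, c] · (cov[c, s] − mean cov[c])
             + shift[module(p), class(case(s))]
             + ε,   ε ~ N(0, noise_sd²)
```

Each planted module is driven by one standard-normal latent per case.
Regions observe `√ρ · L + √(1−ρ) · E` with ρ = 0.7, so module structure
is shared across regions while samples are not duplicated. Loadings are
Uniform(0.6, 1): a latent-factor model keeps within-module correlation
well-posed (for loadings `l₁, l₂` and noise σ the correlation is
`l₁l₂ / √((l₁²+σ²)(l₂²+σ²))`), which is what makes planted-partition
recovery a meaningful acceptance surface for the network stage.

Default design (the study conditions the tests run under): 109 cases,
two regions, 2000 proteins, eight modules of 150–40 members, 26 batches
of 11 channels with one pooled-standard (GIS) channel each (batches
blocked by region), batch offsets N(0, 0.5²) per protein × batch,
noise SD 0.3, 10% batch-structured missingness (a protein drops out of a
whole batch at once, mirroring multiplex acquisition — not cell-wise),
age/sex/PMI slopes of ±0.02/±0.2/±0.01 log2 units on a random 30% of
proteins, and class shifts of −0.5 (AD) on the designated resilience
module and +0.4/+0.6 (AsymAD/AD) on the designated pathology module.

Clinical scores are generated jointly with the latents, never assigned
by fiat: CERAD and Braak discretize the pathology latent (plus small
noise), MMSE discretizes a cognition latent
(`0.7·resilience − 0.8·pathology + 0.35·noise`, MMSE = 25.5 + 3·cog
clipped to 0–30), and the diagnosis class is whatever the classification
rule returns. The discretization cut points were fixed once so the
emergent mix approximates a resilience cohort (roughly 30% Control, 40%
AsymAD, 22% AD, the rest Unclassified). Traits: amyloid and tangles are
exponential (monotone) transforms of the pathology latent; global
cognition and cognitive slope are linear in the resilience and pathology
latents. All coefficients are recorded in `GroundTruth`.

GIS channels carry the batch-mean profile plus noise. The matrices are
exported as linear-scale intensities (`2^(baseline + signal)`) so the
pipeline exercises the full normalization path.

What the generator does **not** emulate: peptide/PSM-level structure,
reporter-ion ratio compression and isolation interference, non-Gaussian
heavy-tailed abundance noise, correlated missingness by abundance
(MNAR), and realistic protein–protein pathway topology beyond block
latents. Passing tests therefore demonstrate correct recovery of planted
statistical structure, not performance on real acquisitions.

## Preprocessing

* **GIS normalization** — per protein per batch,
  `log2(intensity / central tendency of the batch's GIS intensities)`;
  the central tendency is the geometric mean (ratio semantics on the log
  scale; arithmetic mean available by config). Nonpositive intensities
  are treated as missing. Samples are median-centered immediately after
  (i.e., before TAMPOR; the ordering is recorded in the QC output).
* **Missingness filter** — keep proteins observed in strictly more than
  50% of samples.
* **TAMPOR** — alternating two-way median polish: per protein, each
  batch's median offset relative to the protein's median-of-batch-medians
  is subtracted, then per-sample medians are subtracted; iterate until
  the largest absolute adjustment < 1e-4 log2 units or 100 iterations.
  The trace is recorded; alternating median polish can cycle in the last
  ~1e-3 without meeting the tolerance, which is reported as a warning
  status, not an error. Efficacy is asserted as the post-correction
  batch **variance component** (method-of-moments, variance-partition
  semantics): raw between-batch eta² has a chance floor of
  `(k−1)/(N−1)` ≈ 8% for k = 10 batches even on perfectly batch-free
  data, so the component — which is ~0 after correction and ~74% before
  (offset SD 0.5 vs noise SD 0.3) — is the meaningful scale.
* **Connectivity outliers** — per-sample connectivity is the sum of
  signed-weighted sample–sample correlations `((1+r)/2)²`; samples with
  |z| > 3 are removed (the direction is unspecified in the underlying
  rule, so two-sided is the default with a low-only mode by config).
  Outlier removal runs per region.
* **Bootstrap covariate regression** — per protein,
  `abundance ~ diagnosis + age + sex + pmi` refit on 1000 case-level
  bootstrap resamples (both regions of a case move together); the median
  coefficient of each covariate is subtracted times the centered
  covariate. The diagnosis term is estimated but never subtracted, which
  is what protects group contrasts. With `n_bootstrap=1` the "resample"
  is the full sample and the operation reduces to plain OLS adjustment.
  Missing cells are mean-imputed for coefficient estimation only; the
  adjustment touches observed cells alone.

## Consensus network

Biweight midcorrelation uses Tukey weights `w = (1−u²)²·1[|u|<1]`,
`u = (x − median)/(9·MAD)`, with a Pearson fallback for zero-MAD vectors
and an NaN handling scheme in the matrix version that computes per-row
biweight terms on observed values and restricts pairwise sums to common
support (the usual fast approximation; the scalar function is exactly
pairwise-complete). Signed adjacency `((1+c)/2)^β`, β = 7; topological
overlap with the mean-connectivity denominator (min by config); consensus
= componentwise minimum (quantile by config) after rescaling each TOM so
its 95th-percentile off-diagonal value matches the first region's.

Module detection is a simplified dynamic-hybrid tree cut over the
average-linkage dendrogram of 1 − TOM, with a *deepest-qualifying-split*
policy: a branch becomes a module only when no deeper branch qualifies on
its own. A branch qualifies when

1. it holds ≥ `min_module_size` (30) proteins below the static cut
   (0.99 of the height range);
2. its normalized core scatter (mean internal merge height) is at most
   the deep-split bound (0.95 at deep split 4);
3. its gap to the merge context is at least ¾ of the remaining headroom;
4. after iteratively pruning members whose mean overlap with the rest
   falls below 0.3× the branch average, the core still meets the size
   minimum and its mean internal TOM is at least 2× the median
   off-diagonal TOM — the absolute coherence check that keeps pure-noise
   branches (whose dendrogram satisfies the relative criteria) out.

A PAM-style stage then attaches each unassigned protein to its
highest-mean-TOM module, provided that overlap clears both the absolute
coherence floor and 0.3× the module's internal mean. Exact equality with
the reference tree-cut implementation is explicitly not a goal; the
package asserts planted-partition recovery instead (ARI ≥ 0.8 and
per-module Jaccard ≥ 0.6 under the default study conditions — observed
in practice at 1.0).

Eigenproteins are first principal components of the standardized module
submatrix (missing values mean-imputed for the decomposition only, never
written back), scaled to unit variance and oriented so the mean
protein–eigenprotein correlation is non-negative. kME is pairwise-complete
Pearson correlation with p-values from the Student-t transform with n−2
degrees of freedom. Modules merge when the consensus eigenprotein
dissimilarity (maximum over regions of 1 − cor) joins below 0.07 in an
average-linkage tree, iterating to stability; reassignment moves a
protein to its maximal-kME module when its current kME p-value exceeds
0.05 while the better one's does not.

Preservation Zsummary uses a reduced statistic battery: one density
statistic (mean within-module adjacency in the test network) and two
connectivity statistics (correlation of intramodular connectivities and
of within-module adjacency patterns between reference and test), each
standardized against 500 random same-size modules; Zsummary is the
midpoint of the density Z and the median connectivity Z. Degenerate
permutation SDs (e.g., reference = test makes the connectivity
correlations identically 1) produce Z = 0 when the observation matches
the null and a capped value otherwise.

## Statistics

* Module–trait association: biweight midcorrelation with Student-t
  p-values, per region, long-format output.
* Group differences: one-way ANOVA; post hoc either Tukey HSD (the
  figure-legend convention) or all-pairs t-tests with Holm adjustment
  (the methods-text convention) — both are implemented because the two
  sources disagree, and `--posthoc both` emits both. The vectorized
  per-protein version computes Tukey p-values from the studentized-range
  distribution on the pooled MSE and matches the statsmodels
  implementation exactly on single proteins. Significance *counts*
  follow the volcano convention: a protein counts as differentially
  expressed for a contrast when the omnibus ANOVA p < 0.05, signed by
  the contrast difference.
* Variance explained: R² of the simple regression of trait on protein.
* Fisher enrichment: one-tailed (greater) exact test with Haldane 0.5
  odds-ratio correction when a table cell is zero; BH step-up correction.
* Finite-population Z:
  `Z = (r − nR/N) / √(n·(R/N)(1−R/N)(1−(n−1)/(N−1)))`, significant above
  1.96 (two-sided α = 0.05).
* PWAS permutation Z: the observed statistic is the mean score of the
  PWAS symbols falling in a module, with score = −log10 p by default.
  The raw phrasing of the statistic (difference of mean p-values) gives
  enrichment a negative sign; using −log10 p keeps enrichment positive
  (matching the plotted significance convention) and weights heavy tails
  sensibly. The raw-mean-p variant is available by config and is
  sign-flipped so enrichment stays positive in both modes; the choice is
  stamped into the output attrs. Null draws are same-size symbol sets
  from the full tested background without replacement (with-replacement
  by flag); the exact permutation p uses the add-one estimator
  `(#{null ≥ obs} + 1)/(B + 1)`. Null distributions are cached per
  module size, which is what makes 2000 modules × 10,000 permutations
  tractable.
* ROTS: `d = |m₁ − m₂| / (a₁ + a₂·s)` with s the pooled standard error,
  so (a₁, a₂) = (0, 1) is exactly the t-statistic. The grid spans
  a₁ ∈ {0 … 5} with a₂ = 1 plus the fold-change limit (1, 0); top-list
  sizes scan a 12-point log ladder up to K = 900. Reproducibility of a
  candidate is the mean top-k overlap across B = 100 bootstrap dataset
  pairs, standardized against label-permuted bootstrap pairs; the
  maximizing candidate is selected. FDR is the permutation plug-in
  (average count of null statistics ≥ each observed d over its rank),
  with monotonicity in d enforced. Equivalence with the reference
  implementation is asserted only as calibration (null FDR-declared
  fraction ≤ nominal + 0.02), not numerical identity.
* Cross-species overlap: rat symbols map to human through a static
  ortholog table (first occurrence wins on collisions, with a warning);
  the Fisher universe defaults to the conservative intersection of the
  mapped query lists with the module universe (full-universe variant by
  argument); BH per list; stars at q < 0.05 / 0.01 / 0.005.

## Numerical and design choices

* Correlations are clipped to [−1, 1]; constant vectors yield missing
  correlations; fewer than four paired observations yield missing bicor.
* The classification rule resolves the Control/AsymAD overlap (CERAD 1,
  Braak 3, no dementia) in favor of Control only when the Braak-3 proviso
  allows it, and emits an explicit `Unclassified` label so non-matching
  synthetic cases flow through the pipeline instead of crashing it.
* One global seed expands to per-stage child seeds through a fixed stage
  table (`SeedSequence([seed, stage_id])`), so reordering stages cannot
  silently change results; every stage writes a provenance JSON with
  content hashes of inputs and outputs, and reruns skip stages whose
  provenance still matches (a corrupted intermediate fails its output
  hash and is recomputed).
* Sex enters the regression as a single indicator; diagnosis as two
  indicators with Control as the reference level.
* Worked arithmetic note: with GIS intensities 80 and 120 and a sample
  at 98, the geometric-mean reference is √9600 ≈ 97.98 and the log2
  ratio is ≈ 3.0e-4.

## Problem sizes used by the checks

The test suite and `scripts/acceptance.py` run the cohort at 2000
proteins × 100 cases × 2 regions (eight planted modules, 40–150
members), PWAS calibration at 2000 simulated modules × 10,000
permutations over an 8356-symbol background, ROTS at 2000 proteins with
B = 100 and a 3-vs-4 design, covariate regression at 500 proteins ×
1000 bootstraps, and preservation at 500 permutations — sizes chosen so
the whole battery completes in a few minutes on one CPU while keeping
every statistical check at the scale its calibration bands assume.

## Known limitations

* The dynamic tree cut is a simplified reimplementation; branch
  admission thresholds (coherence factor 2, pruning ratio 0.3, PAM ratio
  0.3) were fixed by construction against planted/null behavior and are
  exposed on `NetworkParams` but have not been tuned for weakly
  correlated real-data modules.
* The TAMPOR polish reports (rather than resolves) non-convergent
  cycling below ~1e-3 log2 units.
* The matrix bicor uses per-row (not per-pair) medians and MADs under
  missingness.
* ROTS here covers two-group designs only; no paired or multi-group
  variants.
* GO-style enrichment operates on user-supplied GMT sets; there is no
  ontology DAG traversal or term pruning.
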