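# resilnet

Consensus weighted co-expression network analysis for multiplexed (TMT)
brain proteomics of cognitive resilience, with the full statistical
tooling around it: batch correction, covariate regression, module–trait
statistics, permutation-based resilience-enrichment scoring,
reproducibility-optimized differential expression, and cross-species
module overlap — plus a synthetic-cohort generator with known ground
truth that makes every step testable.

## The scientific problem

Some individuals accumulate substantial Alzheimer's-type pathology
(amyloid plaques, neurofibrillary tangles) yet remain cognitively intact
("asymptomatic AD", AsymAD). Comparing the brain proteomes of Control,
AsymAD, and AD cases across matched tissue regions can expose the protein
systems that track cognitive preservation rather than pathology. The
analysis has several coupled stages, each of which this package
implements as a library function with a thin CLI on top:

1. **Case classification.** Semi-quantitative plaque (CERAD 0–3) and
   tangle (Braak 0–6) scores plus dementia status (MMSE < 24) assign
   Control / AsymAD / AD labels (a Braak stage of exactly 3 requires
   CERAD 0 for Control).
2. **Preprocessing.** Reporter intensities are expressed as log2 ratios
   to each batch's pooled standard (GIS) and median-centered; proteins
   quantified in ≤50% of samples are dropped; batch effects are removed
   by iterative two-way median polish (TAMPOR); samples whose network
   connectivity z-score exceeds 3 SD are removed; age/sex/PMI effects are
   subtracted using median coefficients from 1000 nonparametric bootstrap
   refits while protecting the diagnosis term.
3. **Consensus network.** Biweight midcorrelations are soft-thresholded
   into a signed adjacency, `a_ij = ((1 + bicor_ij)/2)^β` with β = 7,
   converted to topological overlap

   `TOM_ij = (Σ_u a_iu a_uj + a_ij) / (mean(k_i, k_j) + 1 − a_ij)`,

   and the per-region TOMs are combined componentwise (scaled minimum).
   Modules come from dynamic tree cutting of 1 − TOM (deep split 4,
   minimum size 30), eigenproteins (module first principal components)
   are merged at dissimilarity 0.07, and membership is quantified as
   kME = cor(protein, eigenprotein). Module preservation is scored with
   permutation Zsummary statistics (500 permutations).
4. **Statistics.** Eigenprotein–trait biweight midcorrelations, one-way
   ANOVA with Tukey or Holm post hocs, and per-protein variance
   explained; gene-set enrichment by one-tailed Fisher tests (BH
   corrected), a finite-population Z-score (significant above 1.96), and
   a 10,000-permutation Z for enrichment of PWAS (proteome-wide
   association study) hits in modules; a reproducibility-optimized test
   statistic (ROTS; B = 100 bootstrap pairs, top lists up to K = 900)
   for small treated-vs-vehicle designs with permutation FDR; and
   ortholog-mapped Fisher overlap of treatment-responsive proteins with
   the human modules.

Because the original human/rat cohorts are access-controlled, the
`simulate` module generates cohorts with the same statistical structure
(multi-batch TMT design with pooled standards, planted co-expression
modules, batch/covariate/diagnosis effects, traits driven by designated
"pathology" and "resilience" latents, batch-structured missingness) and
records the ground truth so that recovery can be asserted.

## Worked example

```python
from resilnet.simulate import SimDesign, simulate_cohort
from resilnet.preprocess import preprocess_pipeline, PreprocessParams
from resilnet.network import build_consensus_network, NetworkParams
from resilnet.stats import me_trait_correlation

design = SimDesign(n_cases=60, n_proteins=600, module_sizes=(80, 70, 60, 50),
                   n_batches=12, seed=42)
matrices, meta, truth = simulate_cohort(design)
adjusted = {r: preprocess_pipeline(m, meta, PreprocessParams(seed=1))[0]
            for r, m in matrices.items()}
shared = adjusted["BA6"].index.intersection(adjusted["BA37"].index)
net = build_consensus_network({r: a.loc[shared] for r, a in adjusted.items()},
                              NetworkParams(seed=1))
print("module sizes:", net.modules.sizes().to_dict())
traits = meta.loc[~meta["is_gis"]]
mt = me_trait_correlation(net.modules.eigenproteins, traits)
print(mt.reindex(mt["bicor"].abs().sort_values(ascending=False).index)
        .head(4).to_string(index=False))
```

prints

```
module sizes: {'M1': 75, 'M2': 66, 'M3': 56, 'M4': 48}
region module   trait    bicor            p  n
   BA6     M2 amyloid 0.858764 1.729272e-18 60
  BA37     M2 amyloid 0.834587 1.188199e-16 60
  BA37     M2 tangles 0.825250 5.092358e-16 60
   BA6     M2 tangles 0.813433 2.852141e-15 60
```

The four planted modules are recovered near-exactly (80/70/60/50 members
planted; a few proteins are lost to the missingness filter). M2 is the
planted "pathology" module, and its eigenprotein correlates strongly
with amyloid and tangle burden in both regions, as constructed. The
planted "resilience" module (M1) correlates with the cognitive traits
instead — `bicor ≈ 0.6` with global cognition and cognitive slope in
both regions.

The same stages are exposed as CLI subcommands
(`resilnet simulate|classify|preprocess|network|enrich|diffexp|crossmap|run|report`);
`resilnet run --seed 1 --out out/` executes the whole pipeline on a
simulated cohort and writes per-stage outputs with provenance JSONs.

## Layout

- `src/resilnet/simulate.py` — synthetic cohorts, PWAS tables, treatment
  experiments, ortholog maps (ground truth recorded)
- `src/resilnet/preprocess.py` — classification, GIS normalization,
  missingness filter, TAMPOR, connectivity outliers, bootstrap regression
- `src/resilnet/network.py` — bicor, signed adjacency, TOM, consensus,
  module detection, eigenproteins, kME, merging, reassignment, Zsummary
- `src/resilnet/stats.py` — module–trait and group-difference statistics
- `src/resilnet/enrichment.py` — Fisher, finite-population Z, BH,
  PWAS permutation Z, marker-list merging
- `src/resilnet/rots.py` — reproducibility-optimized differential
  expression
- `src/resilnet/crossmap.py` — ortholog mapping and module overlap
- `src/resilnet/pipeline.py`, `src/resilnet/cli.py` — orchestration with
  provenance, CLI
- `docs/methods.md` — the model, algorithmic choices, and limitations
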