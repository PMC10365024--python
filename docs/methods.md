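# Methods

## Model and statistic

The input is a cohort of sample-specific bipartite regulatory networks: T
transcription factors × G target genes, one continuous weight per edge per
sample, collected into an E × N matrix (E = T·G when the bipartite graph is
complete). The package does not infer these networks; it consumes them.

For a pathway with gene set P, the pathway block is every edge whose
*target* gene lies in P (all T TF edges per matched gene; genes absent from
the network are ignored). Each edge is standardized across the N samples
(mean 0, sd 1, divisor N − 1; zero-variance edges are dropped and counted).
PCA then treats the N samples as observations in edge-space. The test
statistic is the PC1 variance fraction λ₁/Σλ of the covariance spectrum —
because rows are standardized this equals correlation-PCA. Loadings are the
unit-norm leading eigenvector over edges; patient scores are the projections
of the centered samples onto it. Eigenvector sign is fixed by making the
largest-magnitude loading positive, so repeated runs and downstream
score/loading pairs are consistent (flipping a PC flips scores and loadings
together; |loading|-based summaries are invariant).

With N < E_p the covariance spectrum has at most N − 1 nonzero eigenvalues;
the fraction is taken over that spectrum as-is, with no truncation
correction.

### Permutation null, p-value, effect size

The null re-runs the identical pipeline on `n_perm` (default 1000) gene sets
of the same size, sampled without replacement from the sampling universe.
The universe is the **intersection** of the pathway-collection gene universe
with the network's target genes: sampling genes that have no edges would
silently shrink null sets. Random sets may include the tested pathway's own
genes (pure random sampling).

The p-value is a one-sample, one-tailed t-test of the null vector against
the observed fraction (alternative: null mean < observed),
t = (obs − mean)/(sd/√n_perm), upper tail of Student's t with n_perm − 1 df.
The effect size is a signed Cohen's d, (obs − mean)/sd, positive when the
observed fraction exceeds the null mean — so the ES ≥ 2 gate only passes
excess-variance pathways. All standard deviations use divisor n − 1.

The t-test treats the permutation mean as the estimand, which makes its
p-values extremely small for any observed value several null-sds out; under
a true null their distribution is U-shaped, not uniform (|t| is of order
√n_perm). They are therefore a ranking/gating device, calibrated jointly
with the variance and effect-size gates, not literal tail probabilities. A
config flag (`pvalue_method="empirical"`) swaps in the empirical permutation
p-value (#{null ≥ obs} + 1)/(n_perm + 1), which *is* uniform under
exchangeability; the uniformity property test runs in that mode.

### Multiple testing and gates

Pathways with more than 200 listed genes, or fewer than 3 genes present in
the network (the lower guard is this package's choice; only the upper bound
is standard), are skipped with a logged reason and excluded from the BH
family — only tested hypotheses are corrected. Defaults gates: BH-adjusted
P < 0.01, PC1 variance ≥ 10%, ES ≥ 2. Results are sorted by adjusted
p-value, then descending ES, then pathway name (full determinism). A
size-bias report bins pathway sizes (<50, 50–100, 100–150, 150–200) and
compares the bin shares of tested vs significant pathways.

### Seeding

Each pathway's null is seeded by `blake2b(global_seed || pathway_name) mod
2³¹`, so results are independent of iteration order and stable under
parallelization; equal (seed, size) arguments to `null_pc1_distribution`
give identical vectors.

## Interpretation layer

* **Edge contributions**: PC1 loadings; squared loadings sum to 1, so under
  equal contribution each edge scores 1/√E_p. Edges with |loading| > 1.5 ×
  that are top contributors (magnitude, because eigenvector sign is
  arbitrary). TFs are ranked by their number of top edges; the hub label
  cutoff is the 95th percentile (linear interpolation) over TFs owning ≥ 1
  top edge — TFs with none are excluded from the percentile population.
* **Patient heterogeneity scores**: PC1 (and PC2) projections; PC1 scores
  have mean 0 and PC1 ⊥ PC2 by construction.
* **Subtyping**: K-means on (PC1, PC2) for k in 2..6 (10 restarts, fixed
  seed), keeping the k that maximizes mean Euclidean silhouette width; ties
  go to the smaller k.
* **Covariate association**: Kruskal–Wallis across levels for categorical
  covariates, Pearson correlation test for numerical ones, on the sample
  intersection; BH across exactly the tests performed in the call,
  significance at adjusted P < 0.05 by default; constant covariates are
  skipped with a reason. Association uses PC1 scores (PC2 available via the
  scores API). Survival modeling is deliberately out of scope: scores are
  exported in a tidy table for external survival tooling.
* **Gene targeting scores**: per sample, the sum of all edge weights
  pointing to a gene (weighted in-degree); linear in the weight matrix.
* **Cohort overlap**: upper-tail hypergeometric probability
  P(X ≥ k) for X ~ Hypergeom(universe, |A|, |B|), summed in log-space so
  tails of order 1e-29 are exact. Probabilities below the double-precision
  floor (~1e-308) underflow to 0; the log-space sum keeps everything above
  that representable.

## Synthetic cohorts

`simulate_cohort` emulates the covariance structure the test consumes, not
the marginal distribution of any particular network-inference method:

    w[(tf,g), s] = μ[(tf,g)] + β · ℓ[(tf,g)] · u[s] · 1[g planted] + ε

with μ ~ N(0, baseline_sd²) per edge, latent factor u ~ N(0,1) per sample,
ε ~ N(0, noise_sd²) i.i.d., and loadings ℓ ~ N(0,1) rescaled to
root-mean-square 1 over the planted edges (Σℓ² = E_p). Under that
normalization the planted block's large-N PC1 share is β²/(β² + noise_sd²),
so β is the factor strength in noise-sd units: β = 0 is an exchangeable
null cohort, β = 1 a signal at parity with noise (≈ 50% share), β = 10
near-deterministic (the closed form is checked as a generator test). The
signal enters **all** TF edges of affected genes, matching the extraction
semantics. Pathways are independent random gene sets, so they may overlap —
as real collections do — and a strong planted factor can lift overlapping
pathways too.

Defaults define the study conditions used throughout the tests and the
acceptance script: T = 20 TFs, G = 500 genes, N = 40 samples, 20 pathways
of 10–50 genes, baseline_sd = noise_sd = 1, n_perm = 100 for scans (a
cohort and permutation depth small enough to run the full calibration and
recovery studies in seconds per seed while keeping E_p per pathway in the
hundreds, comparable in shape to real pathway blocks). Optional covariates:
a categorical grouping (uniform or u-quantile-linked) and a numerical
readout correlated with u at a chosen level.

What passing tests on this generator do **not** show: robustness to the
heavy-tailed, spatially structured weights real message-passing methods
produce, to batch effects, or to correlated noise across edges — only the
latent-factor geometry the statistic targets.

## Numerical choices and edge cases

* PCA via SVD of the centered samples × edges matrix (no explicit
  covariance matrix); oracle tests compare against a direct
  eigendecomposition at 1e-10.
* Degenerate inputs error explicitly: all-zero-variance blocks, rank-0
  matrices, constant nulls (zero sd), PC2 requests on rank-1 data,
  constant covariates (skip with reason), inconsistent overlap counts.
* Missing weights are rejected on load by default; an explicit `drop`
  policy discards affected edges. No imputation.
* Wide-TSV round trips are bit-exact (floats serialized with `repr`, parsed
  with round-trip precision).
* BH via statsmodels (`fdr_bh`), cross-checked against a hand-computed
  step-up in the tests.

## Known limitations

* The t-test p-values are not uniformly distributed under the null (see
  above); gates were designed jointly and the empirical mode is available.
* No parallel execution, streaming PCA, or binary formats; cohorts are held
  in memory.
* Identifier normalisation (symbol mapping between GMT and network) is the
  caller's responsibility; identifiers are opaque case-sensitive strings.
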