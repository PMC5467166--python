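# Methods

This note documents the models implemented in `comod`, the defaults
and why they were chosen, what the synthetic data do and do not
emulate, and the numerical conventions that matter for
reproducibility.

## Network construction

The network is the standard unsigned weighted co-expression
construction: absolute Pearson similarity, elementwise soft power,
topological overlap, dissimilarity.  Conventions:

- The adjacency diagonal is stored as 1 but **connectivity always
  excludes the diagonal** (`k_i = Σ_{j≠i} a_ij`), so self-edges never
  inflate degrees or the TOM denominator.
- The TOM is the unsigned formula
  `ω_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij)` with
  `l_ij = Σ_{u≠i,j} a_iu a_uj`, computed by a vectorized matrix
  product and symmetrized against floating-point drift; it is verified
  against a triple-loop reference implementation to 1e-12 in the test
  suite.
- Scale-free fit: connectivities are binned into 10 equal-width bins,
  empty bins dropped, and log10 empirical frequency is regressed on
  log10 mean connectivity per bin.  The reported R² is invariant to
  rescaling all connectivities (a log–log shift), so using densities
  instead of frequencies would not change the β choice; the slope
  estimates −γ of p(k) ~ k^−γ under the frequency convention.
- β is the smallest grid value (default grid 1–12) reaching R² ≥ 0.8.
  If none qualifies, the best-fitting β is returned with an explicit
  flag rather than an error, since downstream stages remain valid.
- Matrices are dense; the gene count is capped (default 20,000) with a
  clear error, because the quadratic memory cost is the real
  constraint, not correctness.

## Module detection

Modules are branches of an average-linkage hierarchical clustering of
the TOM dissimilarity.  Two cutting modes exist:

- **Adaptive cut (default).**  A fixed absolute height does not
  transfer between networks: the soft power β rescales the whole TOM,
  so within-module dissimilarity may sit near 0.92 for β = 2 but near
  0.995 for β = 6.  The adaptive rule is scale-invariant: every
  candidate height (midpoints between consecutive distinct merge
  heights) is scored by the number of clusters of at least
  `min_module_size` it yields, and the midpoint of the plateau of
  heights achieving the maximum is used — low enough that modules have
  not merged into each other, high enough that each is completely
  assembled.  Because some threshold always produces large chance
  clusters on structureless data, candidate modules are additionally
  required to be *coherent* when the expression matrix is supplied:
  the variance explained by the module's first principal component
  must exceed 2× the Marchenko–Pastur null edge
  `(1 + √(n_genes/n_samples))² / n_genes`.  On simulated null cohorts
  selected chance clusters reach at most ~1.5× the edge while planted
  modules sit at 4–7×, so the factor 2 separates the two regimes with
  a wide margin on both sides.
- **Static cut.**  Passing an explicit `cut_height` reproduces the
  classical fixed-height behaviour, useful when comparing against a
  known dendrogram or when the dissimilarity scale is fixed.

Clusters smaller than `min_module_size` (default 30, a typical
minimum for a stable eigengene) become background (label 0); the rest
are renumbered by decreasing size, ties broken deterministically.

## Eigengenes

The eigengene is the first right singular vector of the standardized
(zero mean, unit SD per gene) members × samples matrix.  Because rows
are centred, the eigengene has exactly zero mean; it has unit
Euclidean norm by construction.  Its sign is aligned to correlate
positively with the mean standardized member profile, so "high
eigengene" means "module genes high".  In the degenerate case where
that mean profile is numerically zero (exactly cancelling members),
the sign is aligned to the first member gene, deterministically, and
`sign_flipped` records whether the raw SVD vector was negated.
`variance_explained` is the first squared singular value over the
total, a scale-free coherence measure.

## Trait association

Binary traits use logistic regression, continuous traits linear
regression, both via statsmodels with Wald p-values (the standard
choice for reporting a β/p pair; likelihood-ratio tests would differ
only in small samples).  Insulin-secretion traits are log-transformed
before fitting because raw secretion is strictly positive and
right-skewed; the association is therefore invariant to rescaling the
secretion units (the intercept absorbs the factor).  The eigengene
predictor is standardized over the analysed samples, making betas
"per SD of module expression" and directly comparable across modules
and filtered subsets.  Sample filters (non-diabetic only, BMI above
the median of the analysed subset, ...) are ordinary predicates on the
phenotype table rather than bespoke options.  Complete separation in
the logistic model yields an explicitly flagged non-converged result
(`converged=False`, NaN estimates) instead of a silently huge beta.
One-sided p-values halve the Wald p when the estimated sign matches
the hypothesized direction and report 1 − p/2 otherwise.

## Enrichment

All overlap tests keep the full 2×2 table.  One-sided enrichment
p-values are exact hypergeometric upper tails; two-sided values follow
Fisher's rule (sum of table probabilities no larger than observed).
Genes absent from the stated universe are dropped with a warning
rather than an error, since array-annotation mismatches are the norm
in cross-platform work.  `capture_fraction` is the fraction of the
query set inside the target (the "49% of open-chromatin genes in the
module" style of statistic); `fold_enrichment` is observed over
expected overlap.  Benjamini–Hochberg correction is the standard
step-up procedure and is tested against its brute-force definition.

Comparing the *connectivity* of a gene set against a background with a
"Fisher test" requires dichotomizing a continuous quantity; the
implemented convention splits k_in at the pooled median and applies a
one-sided Fisher exact test to membership × above-median, with a
rank-sum alternative exposed (`method="ranksum"`) because the
dichotomization is a convention, not a law.  The resampling
region-enrichment statistic pools all resampled background sets into a
single proportion before the one-tailed Fisher test; a per-resample
empirical p would be a reasonable alternative but is weaker with the
typical 100 resamples.

## Signatures and concordance

Signatures are per-gene log2 fold-change / p-value / direction tables.
Without covariates the fold-change is the difference of group means on
the log2 scale with Welch p-values; with covariates each gene is fit
by OLS and the group coefficient reported.  Directional concordance
counts significant test genes whose direction matches the reference;
enrichment over a background universe uses the background's
concordant-DE rate in a Fisher 2×2 (with an exact binomial test
against 0.5 when no background is given).  Consistent-gene
identification (knockdown mimics the disease signature, overexpression
reverses it, both at p < α) depends only on signs and p thresholds, so
it is invariant to monotone transforms of the magnitudes — a property
the tests assert.  Cross-platform intensity detrending regresses one
mean profile on the other through a cubic B-spline basis and returns
residuals plus the reference, removing smooth intensity-dependent
distortion while aligning levels.

## Causal inference test

For a trio (dose L, mediator expression G, outcome T) the causal
verdict requires four conditions: (1) L–T association, (2) L–G
association given T, (3) G–T association given L, and (4) conditional
independence of L and T given G.  Conditions 1–3 are nested-model
F-tests with L factor-coded.  Condition 4 is an equivalence-type test
whose *null* is that a direct effect remains, so small p supports
independence: the null distribution is generated by replacing G with
G\* = fitted(G|L) + permuted residuals — preserving the L–G link while
destroying G's ability to absorb the L→T path — and p₄ is the
add-one-smoothed fraction of permuted conditional F statistics at or
below the observed one.  The omnibus is the intersection–union maximum
of the four components; the reactive model exchanges G and T with the
same permutation stream, which makes the symmetry exact: swapping the
two vectors swaps the causal and reactive omnibus values bit-for-bit.
Defaults: 1,000 permutations, dose levels 0/0.1/1 mM coded as a factor
for F-tests and numerically for reported betas.  Verdicts at level α:
causal or reactive when exactly one omnibus rejects, independent when
neither does, undecided when both do.

Calibration measured by the acceptance script at n = 300 and 500
permutations: type-I error under the independent scenario well below
the nominal 5% (the max-combination is conservative), power above 95%
under the causal scenario, and correct causal/reactive ordering in
essentially all reactive runs.

## Synthetic data

The generator plants the statistical structure the analysis assumes:

- **Expression.**  Per module m a latent factor e_m ~ N(0,1) per
  sample; member genes load on it (`x = u·e_m + baseline + ε`,
  ε ~ N(0, noise_sd²), baseline 8 to resemble log2 intensities).
  Defaults mirror the target study's shape: 64 donors, five 50-gene
  modules in 500 genes, loading 0.8, noise SD 1 — within-module
  correlations around 0.4, i.e. deliberately not trivial to cluster.
- **Labelled set.**  40% of module 1 carries an additive loading boost
  (hub_boost 0.2), emulating a gene set with elevated intramodular
  connectivity.
- **Phenotypes.**  T2D status is Bernoulli with a logistic link on the
  factors (intercept −0.87, giving the study's ~30% prevalence);
  HbA1c and log-secretion are linear in the factors plus noise; age,
  sex and BMI are independent nuisance covariates (BMI ~ N(27, 4²) so
  median splits are meaningful).  Default factor effects: −1.2 (T2D
  logit), −0.5 (HbA1c), +0.5/+0.3 (log secretion) per SD of the
  module-1 factor — low module expression means diabetes, high HbA1c
  and impaired secretion.
- **Perturbation signatures.**  Each covered gene is concordant with
  the reference direction with probability `concordance` and
  discordant otherwise (so the measured concordant fraction estimates
  the parameter directly); `flip` negates the target direction for
  overexpression-style rescue; |log2FC| ~ LogNormal(−1, 0.6) and a
  fraction `alpha_frac` of genes is nominally significant.
- **CIT trios.**  Balanced three-level dose with the numeric dose
  value entering the linear structure; causal, reactive and
  independent scenarios as literal structural equations.

What the generator does **not** emulate: probe-level artifacts, batch
effects, missing data, heavy-tailed noise, correlated nuisance
covariates, or overlapping/nested modules.  Passing tests therefore
demonstrate correctness of the machinery under the assumed factor
model, not robustness to real microarray pathology.

## Numerical conventions

- All randomness flows through `numpy.random.default_rng(seed)`;
  fixed seeds give bit-identical tables, files and test results.
- Similarities and TOM values are clipped to [0, 1] against
  floating-point drift; p-values are floored at the smallest positive
  float and capped at 1.
- Text formats only (TSV/CSV/GMT/JSON), written with `%.17g` so
  round-trips are lossless at double precision.
- Degenerate inputs fail loudly and name the offender: zero-variance
  genes, duplicate ids, non-numeric cells, empty gene sets, single
  dose levels.

## Known limitations

- The adaptive cut assumes modules exist and are separated by a merge
  gap; for hypothesis-free exploration the coherence guard (or a
  static cut plus dendrogram inspection) is essential.
- No signed networks, biweight midcorrelation, module merging by
  eigengene correlation, or block-wise approximations for very large
  gene counts.
- The per-gene OLS in covariate-adjusted signatures is a loop; it is
  fine at desk scale but not optimized for tens of thousands of genes.
- Module counts reported for specific real cohorts depend on
  clustering parameters that published analyses rarely state; they
  are not reproducible targets and the package does not attempt them.
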