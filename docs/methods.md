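# Methods

`eigensig` implements an integrative transcriptomics workflow for merging
expression batches, extracting a phenotype signature, and quantifying
pathway deregulation. This note records the models, the parameters that
matter, and the design choices made where the design was genuinely open.

## Two-step SVD batch merging

Each batch is a genes × samples log2 expression matrix `X` with a binary
phenotype label per sample (lean/obese in the motivating application).
Writing the SVD as `X = U Σ Vᵀ`, the columns of `U` are *eigengenes*
(linear combinations of genes) and the rows of `Vᵀ` are *eigenarrays*.
The merging procedure assumes that batch effects are strong additive
modes that load onto leading eigengenes, while the phenotype of interest
is a weaker but label-separable mode.

1. **Per-batch filtering.** For each batch, the sample expression of
   eigengene *i* is row *i* of `Uᵀ X`. Each row is compared between the
   two phenotype groups with a two-sided two-sample Kolmogorov–Smirnov
   test; `ℓ = argmin_i p_i` picks the eigengene that best separates the
   groups, and components `1 … ℓ−1` are subtracted:
   `X̂ = X − Σ_{i<ℓ} λ_i u_i v_iᵀ`. `ℓ = 1` removes nothing. Ties in the
   argmin break to the smallest index (fewest components removed).
2. **Merging.** Filtered batches are aligned on the intersection of their
   gene sets (sorted lexicographically) and samples are concatenated in
   batch order with provenance recorded.
3. **Second filtering.** The same KS/argmin rule is applied once to the
   merged matrix, using the concatenated phenotype labels. Eigengenes
   stronger than the best phenotype discriminator — the between-batch
   structure that appears upon concatenation — are removed.

Matrices are gene-wise mean-centered before each SVD and the mean is not
restored: eigengene filtering is a statement about variation around the
centroid, and restoring per-batch gene means would reintroduce exactly
the additive offsets the procedure is meant to remove. The KS test uses
the asymptotic null distribution (batches have tens of samples); the
exact small-sample tail is used only as a test oracle. Orthogonality and
energy bookkeeping (‖X‖² = ‖X̂‖² + Σ removed λ²) are enforced in tests at
1e-8 relative to the largest singular value.

## Signature extraction and scoring

The first principal component of the filtered merged matrix assigns each
gene a coefficient; its sign is fixed so the obese group's mean score
exceeds the lean group's (falling back to positive skew, with a warning,
when labels are absent). Genes are ranked by |coefficient| and compared
to a null profile built from isotropic random unit vectors (standard
normal entries, normalized): for each replicate the sorted |entries|
are recorded, giving a per-rank mean and standard deviation ν. A rank
passes when |coeff|₍ᵣ₎ > mean᷊ᵣ + σ·νᵣ with σ = 5 by default; the
signature is the longest contiguous prefix of passing ranks (the
rank-cutoff reading of the threshold curve; an "every passing rank"
variant is available behind a flag). The threshold corresponds to a
two-sided standard-normal tail probability of 2Φ̄(5) ≈ 5.73 × 10⁻⁷. A
Benjamini–Hochberg adjustment of that tail over the gene universe is
what this package would report as an FDR-style companion figure; it is a
reimplementation convention, not a claim about any particular published
adjustment. An empty signature is a valid outcome, not an error.

The per-sample score is `S_j = Σ_k α_{i(k)} X_{ij}` over the selected
genes, reported mean-centered over the scored cohort. Missing signature
genes raise an error naming them; nothing is imputed.

Default null profile: 1000 replicates under a fixed seed. The profile
depends only on the universe size, so one profile can serve many
selections over the same universe (the specificity test exploits this).

## Associations

* `score_regression` — ordinary least squares of a covariate (BMI,
  fasting glucose/insulin) on the score; two-sided t-test of zero slope;
  95% percentile-bootstrap band for the fitted line from 1000 pair
  resamples on a 50-point grid. The point estimate's own line is included
  in the envelope, so the band always contains it; degenerate resamples
  (zero score variance) reuse the point estimate.
* `sample_correlation_pcs` — sample–sample Pearson correlations after
  projecting onto the top 7 principal components, which suppresses the
  isotropic noise floor and makes batch or phenotype block structure
  visible.
* `group_specificity_test` — re-derives the signature on each level of a
  binary grouping (e.g. gender) and compares the gene overlap of the two
  signatures to random splits of the same sizes. Group dependence would
  manifest as an unusually *small* overlap, so the one-sided p-value is
  `(1 + #{null ≤ observed}) / (1 + n_splits)` (add-one rule; never 0).
  Batches where a subset lacks four samples per phenotype are dropped
  from that subset's pipeline rather than failing the whole test.

## Pathway over-representation

For a pathway with `K` genes inside the analysis universe (membership
outside the universe is discarded and counted), the p-value of an
overlap `k` with an `n`-gene signature over an `N`-gene universe is the
upper hypergeometric tail `P(X ≥ k)`. Pathways with `k ≥ 2` are
reported, sorted by p; individual p-values are unadjusted (a BH column
is attached for reference only). The family-level p-value draws `n`
genes uniformly without replacement 10 000 times and counts replicates
with at least the observed number of `k ≥ min_k` pathways, again with
the add-one rule.

## Pathway deregulation scores

For each pathway, gene rows are standardized (zero mean, unit variance
across samples — deregulation is treated as scale-free) and a principal
curve is fitted in the standardized pathway subspace by alternating
projection and conditional expectation from a first-principal-component
initialization. The conditional-expectation step smooths each coordinate
against arc length with a cubic smoothing spline; the smoothing target
is `m · σ̂²` where `σ̂²` is a difference-based residual-variance estimate
(each interior point's deviation from the chord through its neighbours,
normalized by the chord variance factor). This fixed rule reproduces
exactly collinear data exactly (σ̂² = 0) and smooths noisy data at the
noise scale, without a hand-tuned span. Iteration stops when the mean
squared projection distance changes by less than 1e-6 or after 50
passes; non-convergence is recorded on the result, not fatal. Curves are
fitted in the full standardized gene space (no PCA pre-reduction; a
pre-reduction step was considered and rejected as unnecessary at these
pathway sizes).

A sample's PDS is its arc-length position minus the mean position of the
reference group (lean samples, or normal tissue), so reference samples
average to zero per pathway by construction and the curve's arbitrary
endpoint plays no role; changing the zero point would shift all values
by one constant. Orientation is fixed so the non-reference group mean is
non-negative. On exactly linear data the PDS equals the centered signed
projection onto the line (verified to 1e-6). Sample-order invariance
holds for converged fits; on pure isotropic noise the non-converged
iteration is numerically order-sensitive, which is immaterial because
noise pathways carry no interpretable deregulation axis.

## Synthetic cohort generator

The generator emulates the study design the merging method targets:
`K` batches over one shared gene universe; per-(batch, gene) additive
offsets `δ ~ N(0, batch_shift_scale²)` dominating raw between-batch
correlation; a small planted gene program tied to a latent phenotype;
and clinical covariates driven by the same latent axis. Per gene, batch
and sample:

    X = μ_g + δ_bg + d_g · m_g · (effect_size / 2) · t_j + ε,

with baselines `μ_g ~ N(7, 1)` log2 units drawn once and shared across
batches, directions `d_g = ±1`, residual noise `ε ~ N(0, noise_sd²)`,
and `t_j` the latent phenotype `z_j ~ N(0,1)` rescaled by `1/E[z|z>0]`
so that thresholding at the within-batch median yields an obese-minus-
lean mean difference of exactly `effect_size · m_g`. The multipliers
`m_g` decay linearly from `1 + effect_spread` to `1 − effect_spread`
(default spread 0.5, mean 1): real signature coefficient profiles decay
severalfold from the top rank rather than sitting flat, and a flat
profile at `1/√n_planted` would be a degenerate edge case sitting on the
extreme-value null threshold at rank 1. BMI is one global affine map of
the latent phenotype onto 18–45 kg/m² plus `bmi_noise_sd` noise; fasting
glucose (85 + 10z ± 6 mg/dL) and insulin (10 + 4z ± 2.5 µU/mL) are
independent noisy maps of the same axis. Gender is independent of the
phenotype program by default; `n_group_genes`/`group_effect_size` plant
gender-specific phenotype programs (half active in females, half in
males, same decaying profile) to probe the specificity test's power.

Defaults — 4 batches × 20 samples, 500 genes, 20 planted genes,
effect 2 log2 units, offsets of scale 3, noise 0.5 — are the study
conditions used throughout the tests and the acceptance script. The
generator does not emulate probe-level artifacts, platform differences,
missing values, or gene–gene correlation beyond the planted programs;
passing tests therefore demonstrate correctness of the procedures under
the stated additive model, not robustness to every failure mode of real
microarray or RNA-seq data.

## Problem sizes and determinism

Test and acceptance runs use cohorts of 80–120 samples over 120–500
genes, 1000-replicate null profiles, 1000-resample bootstraps, 10 000
family replicates and 20–30 permutation splits; these sizes make every
Monte-Carlo comparison stable at the tolerances asserted. All
randomness flows through `numpy.random.default_rng` seeded explicitly;
two runs with the same configuration are bit-identical. The acceptance
script derives every stage seed from a single `--seed`.

## Known limitations

* The KS-based `argmin` rule can, in principle, remove a component that
  carries phenotype signal when batch structure correlates with the
  phenotype; the procedure follows the literal rule and reports every
  removed component in the `FilterReport`.
* Per-batch gene centering removes purely additive batch offsets by
  itself; the eigengene machinery earns its keep on batch effects with
  sample-dependent loadings, which the additive generator intentionally
  does not produce.
* The contiguous-prefix selection stops at the first failing rank even
  if later ranks pass; the alternative rule is exposed but untested
  against any published gene list.
* Principal-curve fitting on structureless data does not converge within
  the iteration cap (by design, reported not raised).
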