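# eigensig

Merging gene-expression batches by SVD eigengene filtering, extracting a
transcriptomic signature with a 5σ random-vector null, and scoring
pathway deregulation with principal curves.

## The problem

Public expression studies of the same phenotype — say, adipose tissue
from lean and obese donors — come in batches from different platforms
and labs. Concatenating them naively yields a matrix whose dominant
variation is the batch, not the biology: samples correlate with their
batch-mates regardless of phenotype. `eigensig` is for analysts who want
to merge such batches, distill a single per-sample score for the
phenotype, and then ask what the score's genes mean at the pathway
level. Every stage is also exercised end-to-end on a built-in synthetic
cohort generator, so the full workflow is testable without downloading
anything.

## The methods

**Two-step SVD merge.** With `X = U Σ Vᵀ`, the columns of `U` are
eigengenes. For each batch, the eigengene whose sample expression best
separates the two phenotype groups (smallest two-sample KS p-value,
index ℓ) is located, and eigengenes `1…ℓ−1` — everything stronger than
the phenotype — are subtracted. Batches are then aligned on their
common genes and concatenated, and the same rule is applied once more to
remove the between-batch structure that appears on concatenation.

**Signature and score.** The first principal component of the merged
matrix gives each gene a coefficient `α_i`. Ranked |coefficients| are
compared with the per-rank mean + 5σ envelope of sorted |entries| of
random unit vectors; the signature is the longest prefix of ranks above
that curve (two-sided normal tail at 5σ: p ≈ 5.7 × 10⁻⁷). The score of
sample `j` is `S_j = Σ α_i X_{ij}` over signature genes, mean-centered.

**Associations.** OLS regressions of clinical covariates (BMI, fasting
glucose/insulin) on the score with bootstrap confidence bands; top-PC
sample-correlation diagnostics; and a permutation test of whether the
signature is specific to a grouping such as gender (re-derive it per
group, compare the overlap to random splits of the same sizes).

**Enrichment and PDS.** Upper-tail hypergeometric over-representation of
signature genes in pathways (`P(X ≥ k)` for a `K`-gene pathway in an
`N`-gene universe), an empirical family-level p-value for the whole set
of reported pathways, and per-sample pathway deregulation scores: the
arc-length position along a principal curve fitted in each pathway's
standardized gene subspace, zeroed at the reference-group mean.

See `docs/methods.md` for assumptions, parameter defaults, and design
choices.

## Worked example

```sh
python examples/02_signature_and_score.py
```

```
signature size:        18 of 500 genes
selection p-value:     5.733e-07 (two-sided normal tail at 5 sigma)
recall vs planted:     0.90   precision: 1.00
top five genes:
 rank gene_id  coefficient
    1   G0082     0.310436
    2   G0455     0.309123
    3   G0101    -0.305440
    4   G0402     0.284191
    5   G0148    -0.258774

mean score, obese: +4.54   lean: -4.54
```

A synthetic four-batch cohort (80 samples, 500 genes, 20 planted
phenotype genes) is merged, and the 5σ rule selects 18 genes — all of
them planted (precision 1.00), recovering 90% of the planted program.
The score separates the obese and lean groups symmetrically because it
is reported mean-centered. The other scripts in `examples/` demonstrate
batch mixing (01), covariate regressions and the gender-specificity test
(03), pathway over-representation (04) and PDS (05); each prints a short
interpretation alongside its numbers.

The end-to-end pipeline is available as one call:

```python
from eigensig import PipelineConfig, SimConfig, run_pipeline

result = run_pipeline(PipelineConfig(out_dir="run", simulate=SimConfig(seed=0), seed=0))
```

which writes expression, signature, score, enrichment and PDS tables
plus a manifest with all seeds to `run/`.

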