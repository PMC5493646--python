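"""Score-covariate regression, PC-restricted correlation diagnostics and
the random-split signature-specificity permutation test.

``score_regression`` fits ordinary least squares of a clinical covariate
(BMI, fasting glucose/insulin, ...) on the per-sample score, with a
two-sided test of zero slope and a 95% percentile-bootstrap band for the
fitted line.  ``sample_correlation_pcs`` computes sample-sample Pearson
correlations restricted to the top principal components, the diagnostic
that makes batch (before merging) or phenotype (after merging) block
structure visible.  ``group_specificity_test`` asks whether a signature is
specific to a binary grouping (e.g. gender) by re-deriving the signature
on each group separately and comparing the gene overlap to that of random
splits of the same sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .batch import ExpressionBatch, MergedExpression, svd_decompose, two_step_merge
from .signature import (
    NullRankProfile,
    ScoreVector,
    first_pc_coefficients,
    null_rank_profile,
    select_signature,
)

__all__ = [
    "RegressionResult",
    "SpecificityResult",
    "score_regression",
    "sample_correlation_pcs",
    "group_specificity_test",
]


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    pearson_r: float
    p_value: float  # two-sided test of zero slope
    band_grid: np.ndarray  # covariate evaluated at these score values
    band_lower: np.ndarray  # 95% bootstrap band
    band_upper: np.ndarray
    n_samples: int

    def fitted(self, x: np.ndarray | None = None) -> np.ndarray:
        x = self.band_grid if x is None else np.asarray(x)
        return self.intercept + self.slope * x


@dataclass
class SpecificityResult:
    overlap_observed: int
    null_overlaps: np.ndarray
    p_value: float  # fraction of null overlaps <= observed (add-one rule)
    n_splits: int
    group_signatures: tuple[list[str], list[str]] | None = None


def score_regression(
    scores: ScoreVector | pd.Series | np.ndarray,
    covariate: pd.Series | np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    n_grid: int = 50,
) -> RegressionResult:
    """OLS of ``covariate`` on ``scores`` with a bootstrap band.

    The slope's p-value is the two-sided t-test of zero slope.  The band is
    the 2.5/97.5 percentile envelope of fitted lines over ``n_boot``
    resamples of (score, covariate) pairs, evaluated on an ``n_grid``-point
    grid spanning the score range; the point estimate's own fitted line is
    included in the envelope so the band always contains it.
    """
    if isinstance(scores, ScoreVector):
        x = np.asarray(scores.scores, dtype=float)
    else:
        x = np.asarray(scores, dtype=float)
    y = np.asarray(covariate, dtype=float)
    if x.shape != y.shape:
        raise ValueError("scores and covariate must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired finite observations")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance score")
    if np.ptp(y) == 0:
        raise ValueError("zero-variance covariate")

    fit = stats.linregress(x, y)
    grid = np.linspace(x.min(), x.max(), n_grid)
    rng = np.random.default_rng(seed)
    lines = np.empty((n_boot + 1, n_grid))
    lines[0] = fit.intercept + fit.slope * grid
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        xb, yb = x[idx], y[idx]
        if np.ptp(xb) == 0:  # degenerate resample: reuse point estimate
            lines[b + 1] = lines[0]
            continue
        bfit = stats.linregress(xb, yb)
        lines[b + 1] = bfit.intercept + bfit.slope * grid
    lower = np.percentile(lines, 2.5, axis=0)
    upper = np.percentile(lines, 97.5, axis=0)
    # envelope always contains the point estimate's own line
    lower = np.minimum(lower, lines[0])
    upper = np.maximum(upper, lines[0])
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        pearson_r=float(fit.rvalue),
        p_value=float(fit.pvalue),
        band_grid=grid,
        band_lower=lower,
        band_upper=upper,
        n_samples=n,
    )


def sample_correlation_pcs(merged: MergedExpression, n_pcs: int = 7) -> pd.DataFrame:
    """Sample-sample Pearson correlations in top-PC space.

    Samples are projected onto the top ``n_pcs`` principal components of
    the (gene-centered) merged matrix; the returned symmetric matrix holds
    Pearson correlations between the sample projection vectors.
    Restricting to a handful of components suppresses the isotropic noise
    floor that would otherwise wash out block structure.
    """
    if n_pcs < 1:
        raise ValueError("n_pcs must be >= 1")
    X = merged.values.to_numpy(dtype=float)
    if n_pcs > min(X.shape):
        raise ValueError(f"n_pcs={n_pcs} exceeds matrix rank bound {min(X.shape)}")
    Xc = X - X.mean(axis=1, keepdims=True)
    E = svd_decompose(Xc)
    coords = (E.singular_values[:n_pcs, None] * E.eigenarrays[:n_pcs, :]).T
    corr = np.corrcoef(coords)
    return pd.DataFrame(corr, index=merged.sample_ids, columns=merged.sample_ids)


def _signature_genes_for_samples(
    batches: Sequence[ExpressionBatch],
    sample_ids: set[str],
    profile: NullRankProfile,
    sigma: float,
    status_column: str,
) -> list[str]:
    sub = []
    for b in batches:
        keep = [s for s in b.sample_ids if s in sample_ids]
        if len(keep) < 4:
            continue
        s = b.subset_samples(keep)
        counts = s.metadata[status_column].value_counts()
        if len(counts) < 2 or counts.min() < 2:
            continue
        sub.append(s)
    if not sub:
        raise ValueError("no usable batch after subsetting")
    merged, _ = two_step_merge(sub, status_column=status_column)
    coeffs = first_pc_coefficients(merged, status_column=status_column)
    sig = select_signature(coeffs, profile, sigma=sigma)
    return sig.selected_genes


def group_specificity_test(
    batches: Sequence[ExpressionBatch],
    grouping: pd.Series,
    n_splits: int = 100,
    seed: int = 0,
    sigma: float = 5.0,
    null_replicates: int = 500,
    status_column: str = "status",
    min_group_phenotype: int = 4,
) -> SpecificityResult:
    """Permutation test of signature specificity to a binary grouping.

    The signature pipeline (two-step merge, first PC, sigma-threshold
    selection) is run on group-A samples only and on group-B samples only;
    the observed statistic is the size of the gene overlap between the two
    signatures.  The null distribution repeats this with ``n_splits``
    random A/B splits of the same sizes.  Group dependence would show up as
    an unusually *small* overlap, so
    ``p = (1 + #{null overlap <= observed}) / (1 + n_splits)``.
    """
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1 (null undefined otherwise)")
    all_sample_ids = [s for b in batches for s in b.sample_ids]
    grouping = grouping.reindex(all_sample_ids)
    if grouping.isna().any():
        raise ValueError("grouping must cover every sample")
    levels = pd.unique(grouping)
    if len(levels) != 2:
        raise ValueError(f"grouping must be binary, got {list(levels)}")
    group_a = grouping == levels[0]
    status = pd.concat([b.metadata[status_column] for b in batches]).reindex(
        all_sample_ids
    )
    for level, mask in ((levels[0], group_a), (levels[1], ~group_a)):
        counts = status[mask.to_numpy()].value_counts()
        if len(counts) < 2 or counts.min() < min_group_phenotype:
            raise ValueError(
                f"group {level!r} too small: need >= {min_group_phenotype} "
                f"samples per phenotype"
            )

    # shared gene universe => one null profile serves observed and null runs
    universe = set(batches[0].gene_ids)
    for b in batches[1:]:
        universe &= set(b.gene_ids)
    profile = null_rank_profile(len(universe), n_replicates=null_replicates, seed=seed)

    def overlap_for(mask: np.ndarray) -> tuple[int, list[str], list[str]]:
        ids_a = {s for s, m in zip(all_sample_ids, mask) if m}
        ids_b = set(all_sample_ids) - ids_a
        genes_a = _signature_genes_for_samples(
            batches, ids_a, profile, sigma, status_column
        )
        genes_b = _signature_genes_for_samples(
            batches, ids_b, profile, sigma, status_column
        )
        return len(set(genes_a) & set(genes_b)), genes_a, genes_b

    observed_mask = group_a.to_numpy()
    observed, genes_a, genes_b = overlap_for(observed_mask)

    rng = np.random.default_rng(seed)
    null = np.empty(n_splits, dtype=int)
    for s in range(n_splits):
        null[s], _, _ = overlap_for(rng.permutation(observed_mask))
    p = (1 + int((null <= observed).sum())) / (1 + n_splits)
    return SpecificityResult(
        overlap_observed=observed,
        null_overlaps=null,
        p_value=p,
        n_splits=n_splits,
        group_signatures=(genes_a, genes_b),
    )
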