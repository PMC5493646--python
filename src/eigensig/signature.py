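"""Signature extraction via the first principal component and a 5-sigma
random-vector null, and per-sample score computation.

After batch effects are removed, the first principal component of the
merged genes x samples matrix is a unit vector assigning every gene a
coefficient.  Genes are ranked by absolute coefficient and compared, rank
by rank, to the profile of sorted absolute entries of isotropic random
unit vectors of the same dimension: a gene is kept while its coefficient
magnitude exceeds the null's per-rank mean plus ``sigma`` times the
per-rank standard deviation.  The signature is the longest contiguous
prefix of ranks passing this test (the rank-cutoff reading of the
threshold curve); an alternative rule keeping every individually-passing
rank is available via ``contiguous=False``.

The per-sample score is the signed linear combination

    S_j = sum_k alpha_{i(k)} X_{i j}

of log2 expression over the selected genes, reported mean-centered over
the scored cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .batch import ExpressionBatch, MergedExpression, svd_decompose

__all__ = [
    "NullRankProfile",
    "Signature",
    "ScoreVector",
    "first_pc_coefficients",
    "null_rank_profile",
    "select_signature",
    "compute_score",
]


@dataclass
class NullRankProfile:
    """Per-rank mean and standard deviation of sorted absolute entries of
    random unit vectors (the ranked-coefficient profile of a randomized
    score)."""

    n_replicates: int
    rank_means: np.ndarray  # non-increasing
    rank_sds: np.ndarray
    seed: int

    def __len__(self) -> int:
        return self.rank_means.shape[0]


@dataclass
class Signature:
    """Ordered gene/coefficient list defining the score.

    ``gene_ids`` are sorted by absolute coefficient, descending;
    ``n_selected`` of them make up the signature.  ``selection_pvalue`` is
    the two-sided standard-normal tail probability at ``sigma_threshold``.
    """

    gene_ids: list[str]
    coefficients: np.ndarray
    n_selected: int
    sigma_threshold: float
    selection_pvalue: float
    universe_size: int

    @property
    def selected_genes(self) -> list[str]:
        return self.gene_ids[: self.n_selected]

    @property
    def selected_coefficients(self) -> np.ndarray:
        return self.coefficients[: self.n_selected]

    def to_frame(self) -> pd.DataFrame:
        """Table of the selected genes: rank, gene id, coefficient."""
        return pd.DataFrame(
            {
                "rank": np.arange(1, self.n_selected + 1),
                "gene_id": self.selected_genes,
                "coefficient": self.selected_coefficients,
            }
        )


@dataclass
class ScoreVector:
    """Mean-centered per-sample scores; ``reference_mean`` is the cohort
    mean subtracted during centering."""

    sample_ids: list[str]
    scores: np.ndarray
    reference_mean: float

    def to_series(self) -> pd.Series:
        return pd.Series(self.scores, index=self.sample_ids, name="score")


def first_pc_coefficients(
    merged: MergedExpression,
    status_column: str = "status",
    positive_group: str = "obese",
) -> pd.Series:
    """Unit-norm first-principal-component gene coefficients.

    The sign is fixed so that the mean score of ``positive_group`` samples
    exceeds the other group's; if ``status_column`` is absent the vector is
    oriented toward positive skewness instead (flagged via a warning).
    """
    X = merged.values.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need at least two samples")
    Xc = X - X.mean(axis=1, keepdims=True)
    if not np.any(Xc):
        raise ValueError("zero-variance matrix has no principal component")
    E = svd_decompose(Xc)
    pc = E.eigengenes[:, 0]
    scores = pc @ Xc
    if status_column in merged.metadata.columns:
        labels = merged.metadata[status_column].to_numpy()
        pos = scores[labels == positive_group].mean()
        neg = scores[labels != positive_group].mean()
        if pos < neg:
            pc = -pc
    else:
        import warnings

        warnings.warn(
            "no phenotype labels: orienting first PC toward positive skew",
            stacklevel=2,
        )
        if stats.skew(scores) < 0:
            pc = -pc
    return pd.Series(pc, index=merged.gene_ids, name="coefficient")


def null_rank_profile(
    universe_size: int, n_replicates: int = 1000, seed: int = 0
) -> NullRankProfile:
    """Ranked-coefficient null profile from isotropic random unit vectors.

    Each replicate draws a standard-normal vector of length
    ``universe_size``, normalizes it to unit length, and sorts the absolute
    entries in decreasing order; the profile is the per-rank mean and
    standard deviation over replicates.
    """
    if universe_size < 2:
        raise ValueError("universe_size must be >= 2")
    if n_replicates < 100:
        raise ValueError("need at least 100 replicates for a stable profile")
    rng = np.random.default_rng(seed)
    V = rng.standard_normal((n_replicates, universe_size))
    V /= np.linalg.norm(V, axis=1, keepdims=True)
    A = np.sort(np.abs(V), axis=1)[:, ::-1]
    return NullRankProfile(
        n_replicates=n_replicates,
        rank_means=A.mean(axis=0),
        rank_sds=A.std(axis=0, ddof=1),
        seed=seed,
    )


def select_signature(
    coefficients: pd.Series | np.ndarray,
    profile: NullRankProfile,
    sigma: float = 5.0,
    contiguous: bool = True,
) -> Signature:
    """Keep the genes whose ranked |coefficient| exceeds the random-vector
    null by ``sigma`` standard deviations.

    Rank r passes when ``|coeff|_(r) > rank_means[r] + sigma * rank_sds[r]``.
    With ``contiguous=True`` (default) the signature is the longest prefix
    of passing ranks; otherwise every passing rank is kept (reported in
    rank order, so coefficients stay sorted).  An empty signature
    (``n_selected = 0``) is a valid outcome, not an error.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if isinstance(coefficients, pd.Series):
        gene_ids = list(coefficients.index)
        coeffs = coefficients.to_numpy(dtype=float)
    else:
        coeffs = np.asarray(coefficients, dtype=float)
        gene_ids = [f"g{i}" for i in range(coeffs.size)]
    if coeffs.size != len(profile):
        raise ValueError(
            f"coefficient vector length {coeffs.size} does not match "
            f"null profile length {len(profile)}"
        )
    order = np.argsort(-np.abs(coeffs), kind="stable")
    ranked = np.abs(coeffs[order])
    passing = ranked > profile.rank_means + sigma * profile.rank_sds
    if contiguous:
        failures = np.flatnonzero(~passing)
        n_selected = int(failures[0]) if failures.size else coeffs.size
        keep = order
    else:
        n_selected = int(passing.sum())
        keep = np.concatenate([order[passing], order[~passing]])
    selection_pvalue = float(2.0 * stats.norm.sf(sigma))
    return Signature(
        gene_ids=[gene_ids[i] for i in keep],
        coefficients=coeffs[keep],
        n_selected=n_selected,
        sigma_threshold=float(sigma),
        selection_pvalue=selection_pvalue,
        universe_size=coeffs.size,
    )


def compute_score(
    signature: Signature,
    batch: ExpressionBatch | MergedExpression | pd.DataFrame,
) -> ScoreVector:
    """Score every sample of ``batch`` with the signature.

    ``S_j = sum alpha_i X_ij`` over the selected genes, mean-centered over
    the scored cohort.  All signature genes must be present; missing genes
    raise an error naming them (no silent imputation).
    """
    values = batch if isinstance(batch, pd.DataFrame) else batch.values
    missing = [g for g in signature.selected_genes if g not in values.index]
    if missing:
        raise KeyError(f"signature genes missing from expression matrix: {missing}")
    sub = values.loc[signature.selected_genes].to_numpy(dtype=float)
    raw = signature.selected_coefficients @ sub
    mean = float(raw.mean()) if raw.size else 0.0
    return ScoreVector(
        sample_ids=list(values.columns),
        scores=raw - mean,
        reference_mean=mean,
    )
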