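"""Two-step SVD eigengene filtering and merging of expression batches.

The merging strategy treats each batch's genes x samples log2 expression
matrix through its singular value decomposition

    X = U S V^T,

where the columns of ``U`` are *eigengenes* (linear combinations of genes)
and the rows of ``V^T`` are *eigenarrays* (linear combinations of samples).
Systematic non-biological variation (a batch effect) typically loads onto
the leading eigengenes.  The method removes, in two passes, every eigengene
stronger than the one that best discriminates the phenotype of interest:

1. per batch, filter out eigengenes ``1 .. l-1`` where ``l`` is the index
   of the eigengene whose sample expression best separates the two
   phenotype groups (smallest two-sample Kolmogorov-Smirnov p-value);
2. align the filtered batches on their common gene universe and
   concatenate samples;
3. repeat the same filtering once on the merged matrix, where the dominant
   eigengenes now capture between-batch structure.

After step 1 the phenotype is the strongest remaining effect within each
batch, so the second pass removes eigengenes stronger than it -- i.e. the
batch effects that appear upon concatenation.

Matrices are gene-wise mean-centered before each SVD (and the mean is not
restored): eigengene filtering is only meaningful around the data centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionBatch",
    "EigenSystem",
    "FilterReport",
    "MergedExpression",
    "svd_decompose",
    "eigengene_phenotype_pvalues",
    "select_ell",
    "filter_eigengenes",
    "merge",
    "two_step_merge",
]

#: relative tolerance (w.r.t. largest singular value) for orthogonality
#: and reconstruction checks
SVD_RTOL = 1e-8

REQUIRED_METADATA = ("batch", "status")


@dataclass
class ExpressionBatch:
    """One batch: a genes x samples log2 expression matrix plus metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample id.
    metadata
        Per-sample table indexed by sample id.  Must contain at least a
        ``batch`` label and a ``status`` column (``"lean"``/``"obese"``);
        ``bmi``, ``gender``, ``fpg``, ``fpi`` are carried through when
        present.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValueError("duplicate gene ids in expression matrix")
        if not self.values.columns.is_unique:
            raise ValueError("duplicate sample ids in expression matrix")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression matrix contains non-finite values")
        if list(self.values.columns) != list(self.metadata.index):
            raise ValueError("metadata index must match sample columns")
        missing = [c for c in REQUIRED_METADATA if c not in self.metadata.columns]
        if missing:
            raise ValueError(f"metadata missing required columns: {missing}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionBatch":
        """Restrict the batch to ``sample_ids`` (order preserved)."""
        sample_ids = list(sample_ids)
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples not in batch: {missing}")
        return ExpressionBatch(
            values=self.values[sample_ids].copy(),
            metadata=self.metadata.loc[sample_ids].copy(),
        )


@dataclass
class EigenSystem:
    """SVD factors of an expression matrix.

    ``eigengenes`` holds the left singular vectors as columns (gene space),
    ``eigenarrays`` the right singular vectors as rows (sample space), and
    ``singular_values`` the non-increasing singular values.  ``L`` equals
    ``min(n_genes, n_samples)``.
    """

    eigengenes: np.ndarray  # (n_genes, L)
    eigenarrays: np.ndarray  # (L, n_samples)
    singular_values: np.ndarray  # (L,)

    @property
    def L(self) -> int:
        return self.singular_values.shape[0]

    def reconstruct(self) -> np.ndarray:
        return (self.eigengenes * self.singular_values) @ self.eigenarrays


@dataclass
class FilterReport:
    """Per-stage record of the two-step merge: selected ``l`` values and the
    Kolmogorov-Smirnov p-value vector each selection was based on."""

    per_batch_ell: list[int] = field(default_factory=list)
    per_batch_ks_pvalues: list[np.ndarray] = field(default_factory=list)
    merged_ell: int | None = None
    merged_ks_pvalues: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "per_batch_ell": [int(e) for e in self.per_batch_ell],
            "per_batch_ks_pvalues": [
                [float(p) for p in v] for v in self.per_batch_ks_pvalues
            ],
            "merged_ell": None if self.merged_ell is None else int(self.merged_ell),
            "merged_ks_pvalues": None
            if self.merged_ks_pvalues is None
            else [float(p) for p in self.merged_ks_pvalues],
        }


@dataclass
class MergedExpression:
    """Filtered batches aligned on the common gene universe, samples
    concatenated in batch order with per-sample provenance."""

    values: pd.DataFrame  # genes x samples
    provenance: pd.Series  # batch label per sample
    metadata: pd.DataFrame

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


def svd_decompose(values: np.ndarray | pd.DataFrame) -> EigenSystem:
    """Thin SVD of a genes x samples matrix.

    Raises
    ------
    ValueError
        If the matrix has non-finite entries or fewer than two samples.
    """
    X = np.asarray(values, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    if X.shape[1] < 2:
        raise ValueError("need at least two samples")
    if not np.isfinite(X).all():
        raise ValueError("matrix contains non-finite entries")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    return EigenSystem(eigengenes=U, eigenarrays=Vt, singular_values=s)


def eigengene_phenotype_pvalues(
    eigensystem: EigenSystem,
    values: np.ndarray | pd.DataFrame,
    labels: Sequence[str] | np.ndarray,
    method: str = "asymp",
) -> np.ndarray:
    """Two-sample KS p-value per eigengene, lean vs obese.

    The expression of the i-th eigengene across samples is row i of
    ``U^T X``; each row is compared between the two phenotype groups with a
    two-sided two-sample Kolmogorov-Smirnov test.  The asymptotic null
    distribution is used by default (batches have tens of samples);
    ``method`` is forwarded to :func:`scipy.stats.ks_2samp`.
    """
    X = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if labels.shape[0] != X.shape[1]:
        raise ValueError("one label per sample required")
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"expected exactly two phenotype groups, got {list(groups)}")
    mask = labels == groups[0]
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise ValueError("each phenotype group needs at least two samples")
    projections = eigensystem.eigengenes.T @ X  # (L, n_samples)
    pvals = np.empty(projections.shape[0])
    for i, row in enumerate(projections):
        pvals[i] = stats.ks_2samp(row[mask], row[~mask], method=method).pvalue
    return pvals


def select_ell(pvalues: np.ndarray) -> int:
    """1-based index of the eigengene best discriminating the phenotype.

    ``l = argmin_i p_i`` (equivalently ``argmax_i -log p_i``); ties break
    to the smallest index, which removes the fewest eigengenes.  Eigengenes
    ``1 .. l-1`` are slated for removal; ``l = 1`` means filter nothing.
    """
    pvalues = np.asarray(pvalues)
    if pvalues.size == 0:
        raise ValueError("empty p-value vector")
    return int(np.argmin(pvalues)) + 1


def filter_eigengenes(
    values: np.ndarray | pd.DataFrame,
    eigensystem: EigenSystem,
    ell: int,
) -> np.ndarray:
    """Remove the first ``l - 1`` eigengene components from a matrix.

    Returns ``X - sum_{i<l} s_i (u_i v_i^T)``.  With ``l = 1`` the sum is
    empty and the input is returned unchanged.
    """
    X = np.asarray(values, dtype=float)
    if not 1 <= ell <= eigensystem.L:
        raise ValueError(f"ell={ell} out of range [1, {eigensystem.L}]")
    k = ell - 1
    if k == 0:
        return X.copy()
    U = eigensystem.eigengenes[:, :k]
    s = eigensystem.singular_values[:k]
    Vt = eigensystem.eigenarrays[:k, :]
    return X - (U * s) @ Vt


def merge(batches: Sequence[ExpressionBatch]) -> MergedExpression:
    """Align batches on the intersection of their gene sets and concatenate
    samples in batch order.

    The common gene universe is sorted lexicographically.  Sample ids must
    be unique across batches.
    """
    if not batches:
        raise ValueError("no batches to merge")
    universe = set(batches[0].gene_ids)
    for b in batches[1:]:
        universe &= set(b.gene_ids)
    if not universe:
        raise ValueError("gene-id intersection across batches is empty")
    genes = sorted(universe)

    all_samples: list[str] = []
    for b in batches:
        all_samples.extend(b.sample_ids)
    if len(set(all_samples)) != len(all_samples):
        raise ValueError("duplicate sample ids across batches")

    values = pd.concat([b.values.loc[genes] for b in batches], axis=1)
    metadata = pd.concat([b.metadata for b in batches], axis=0)
    provenance = pd.Series(
        np.concatenate([[str(b.metadata["batch"].iloc[0])] * b.n_samples for b in batches]),
        index=values.columns,
        name="batch",
    )
    return MergedExpression(values=values, provenance=provenance, metadata=metadata)


def _center_genes(X: np.ndarray) -> np.ndarray:
    return X - X.mean(axis=1, keepdims=True)


def _filter_matrix(
    X: np.ndarray, labels: np.ndarray, ks_method: str
) -> tuple[np.ndarray, int, np.ndarray]:
    """Gene-center, decompose, select l by the KS rule and filter."""
    Xc = _center_genes(X)
    E = svd_decompose(Xc)
    pvals = eigengene_phenotype_pvalues(E, Xc, labels, method=ks_method)
    ell = select_ell(pvals)
    return filter_eigengenes(Xc, E, ell), ell, pvals


def two_step_merge(
    batches: Sequence[ExpressionBatch],
    status_column: str = "status",
    ks_method: str = "asymp",
) -> tuple[MergedExpression, FilterReport]:
    """SVD-filter each batch, merge, and SVD-filter the merged matrix.

    Every batch must carry both phenotype groups in ``status_column``.
    Each matrix is gene-wise mean-centered before its SVD and the centering
    is not undone.  Returns the filtered merged expression plus a
    :class:`FilterReport` with all selected ``l`` values and KS p-value
    vectors.
    """
    report = FilterReport()
    filtered: list[ExpressionBatch] = []
    for b in batches:
        labels = b.metadata[status_column].to_numpy()
        Xhat, ell, pvals = _filter_matrix(b.values.to_numpy(), labels, ks_method)
        report.per_batch_ell.append(ell)
        report.per_batch_ks_pvalues.append(pvals)
        filtered.append(
            ExpressionBatch(
                values=pd.DataFrame(Xhat, index=b.gene_ids, columns=b.sample_ids),
                metadata=b.metadata,
            )
        )
    merged = merge(filtered)
    labels = merged.metadata[status_column].to_numpy()
    Yhat, ell, pvals = _filter_matrix(merged.values.to_numpy(), labels, ks_method)
    report.merged_ell = ell
    report.merged_ks_pvalues = pvals
    merged_filtered = MergedExpression(
        values=pd.DataFrame(Yhat, index=merged.gene_ids, columns=merged.sample_ids),
        provenance=merged.provenance,
        metadata=merged.metadata,
    )
    return merged_filtered, report
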