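"""Pathway deregulation scores (PDS) via principal curves.

A pathway's deregulation in a sample is quantified by the sample's
position along a smooth one-dimensional curve fitted through the middle
of the data in the subspace spanned by the pathway's genes (a principal
curve in the Hastie-Stuetzle sense: each curve point is the average of
the samples projecting onto it).  The curve is fitted by alternating

1. projection: assign each sample the arc-length position of its nearest
   point on the current curve (a polyline through the fitted vertices);
2. conditional expectation: smooth each gene coordinate as a function of
   arc length with a cubic smoothing spline whose smoothing level is set
   from a difference-based estimate of the residual variance (so exactly
   linear data is reproduced exactly and noisy data is smoothed at the
   noise scale), starting from the first-principal-component
   parameterization,

until the mean squared projection distance stabilizes.  The PDS of a
sample is its arc-length position minus the mean position of a declared
reference group (e.g. lean samples, or normal tissue), so the reference
group averages to zero by construction and the curve's arbitrary endpoint
plays no role; the orientation is fixed so the non-reference group mean
is non-negative.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import UnivariateSpline

from .batch import MergedExpression
from .enrichment import GeneSetCollection

__all__ = ["PrincipalCurve", "PDSResult", "fit_principal_curve", "compute_pds", "pds_matrix"]

logger = logging.getLogger(__name__)


@dataclass
class PrincipalCurve:
    """Fitted curve: ordered vertices in pathway-gene space, the cumulative
    arc length at each vertex, and per-sample arc-length positions."""

    vertices: np.ndarray  # (n_vertices, n_genes), ordered along the curve
    arc_positions: np.ndarray  # cumulative arc length at each vertex, from 0
    sample_positions: np.ndarray  # arc-length position of each input sample
    converged: bool
    n_iterations: int
    projection_mse: float


@dataclass
class PDSResult:
    pathway_name: str
    sample_ids: list[str]
    pds: np.ndarray  # signed arc-length values, zeroed at reference mean
    reference_ids: list[str]

    def to_series(self) -> pd.Series:
        return pd.Series(self.pds, index=self.sample_ids, name=self.pathway_name)


def _cumulative_arclength(vertices: np.ndarray) -> np.ndarray:
    steps = np.linalg.norm(np.diff(vertices, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(steps)])


def _project_to_polyline(
    points: np.ndarray, vertices: np.ndarray, arcs: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Arc-length position and squared distance of each point's nearest
    point on the polyline through ``vertices``."""
    n = points.shape[0]
    best_d2 = np.full(n, np.inf)
    best_pos = np.zeros(n)
    for i in range(len(vertices) - 1):
        a, b = vertices[i], vertices[i + 1]
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0.0:
            t = np.zeros(n)
        else:
            t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
        proj = a + t[:, None] * ab
        d2 = ((points - proj) ** 2).sum(axis=1)
        better = d2 < best_d2
        best_d2[better] = d2[better]
        best_pos[better] = arcs[i] + t[better] * np.sqrt(denom)
    if len(vertices) == 1:
        best_d2 = ((points - vertices[0]) ** 2).sum(axis=1)
        best_pos = np.zeros(n)
    return best_pos, best_d2


def _residual_variance(x: np.ndarray, y: np.ndarray) -> float:
    """Difference-based residual-variance estimate (Gasser-Sroka-
    Jennen-Steinmetz): deviation of each interior point from the chord
    through its neighbours, normalized by the chord-interpolation variance
    factor.  Exactly zero for data on a straight line, whatever the
    spacing of ``x``."""
    if x.size < 3:
        return 0.0
    span = x[2:] - x[:-2]
    # guard: distinct x values guaranteed by caller, span > 0
    a = (x[2:] - x[1:-1]) / span
    b = (x[1:-1] - x[:-2]) / span
    e = a * y[:-2] + b * y[2:] - y[1:-1]
    c = a**2 + b**2 + 1.0
    return float(np.mean(e**2 / c))


def _smooth_coordinates(lam: np.ndarray, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Expected point at each unique arc position: smoothing-spline fit of
    every coordinate against arc length (duplicate positions averaged).

    The FITPACK smoothing target per coordinate is ``m * var_est`` with
    ``var_est`` the difference-based residual variance -- zero for
    collinear data (the line is reproduced exactly), about the noise
    variance otherwise."""
    order = np.argsort(lam, kind="stable")
    lam_sorted = lam[order]
    pts_sorted = points[order]
    uniq, inverse = np.unique(lam_sorted, return_inverse=True)
    means = np.zeros((uniq.size, points.shape[1]))
    counts = np.bincount(inverse).astype(float)
    for d in range(points.shape[1]):
        sums = np.bincount(inverse, weights=pts_sorted[:, d])
        means[:, d] = sums / counts
    if uniq.size < 4:
        # too few distinct positions for a cubic spline: per-position means
        return uniq, means
    fitted = np.empty_like(means)
    with warnings.catch_warnings():
        # FITPACK warns when it cannot meet a very small smoothing target
        # exactly; the returned near-interpolating spline is what we want
        warnings.simplefilter("ignore", UserWarning)
        for d in range(points.shape[1]):
            y = means[:, d]
            s = uniq.size * _residual_variance(uniq, y)
            spl = UnivariateSpline(uniq, y, k=3, s=s)
            fitted[:, d] = spl(uniq)
    return uniq, fitted


def fit_principal_curve(
    points: np.ndarray | pd.DataFrame,
    tol: float = 1e-6,
    max_iter: int = 50,
) -> PrincipalCurve:
    """Fit a principal curve to a samples x genes matrix.

    Initialization is the first-principal-component parameterization;
    iteration stops when the mean squared projection distance changes by
    less than ``tol`` or after ``max_iter`` passes (non-convergence is
    recorded on the result, not fatal).
    """
    P = np.asarray(points, dtype=float)
    if P.ndim != 2 or P.shape[0] < 5:
        raise ValueError("need at least 5 samples")
    if P.shape[1] < 2:
        raise ValueError("need at least 2 pathway genes")
    if not np.isfinite(P).all():
        raise ValueError("non-finite values in input")

    center = P.mean(axis=0)
    Pc = P - center
    # PC1 initialization
    _, _, Vt = np.linalg.svd(Pc, full_matrices=False)
    lam = Pc @ Vt[0]

    prev_mse = np.inf
    converged = False
    n_iter = 0
    sample_pos = lam - lam.min()
    vertices = None
    arcs = None
    for n_iter in range(1, max_iter + 1):
        uniq_lam, vertices = _smooth_coordinates(lam, Pc)
        if len(uniq_lam) < 2:
            # all samples at one point: zero-length curve
            arcs = np.zeros(1)
            sample_pos = np.zeros(P.shape[0])
            converged = True
            prev_mse = 0.0
            break
        arcs = _cumulative_arclength(vertices)
        sample_pos, d2 = _project_to_polyline(Pc, vertices, arcs)
        mse = float(d2.mean())
        if abs(prev_mse - mse) < tol:
            converged = True
            prev_mse = mse
            break
        prev_mse = mse
        lam = sample_pos

    return PrincipalCurve(
        vertices=(vertices if vertices is not None else Pc[:1]) + center,
        arc_positions=arcs if arcs is not None else np.zeros(1),
        sample_positions=sample_pos,
        converged=converged,
        n_iterations=n_iter,
        projection_mse=float(prev_mse) if np.isfinite(prev_mse) else 0.0,
    )


def compute_pds(
    curve: PrincipalCurve,
    sample_ids: Sequence[str],
    reference_ids: Sequence[str],
    pathway_name: str = "",
) -> PDSResult:
    """Signed arc-length deregulation values, zeroed at the reference mean.

    Each sample's PDS is its arc-length position minus the mean position of
    the reference samples; the sign is flipped if needed so the mean over
    non-reference samples is >= 0.  Changing the zero point (e.g. to a
    curve endpoint) would shift every value by the same constant.
    """
    sample_ids = list(sample_ids)
    if len(sample_ids) != curve.sample_positions.shape[0]:
        raise ValueError("sample_ids length must match fitted positions")
    reference_ids = list(reference_ids)
    if not reference_ids:
        raise ValueError("reference_ids must be non-empty")
    missing = [r for r in reference_ids if r not in set(sample_ids)]
    if missing:
        raise ValueError(f"reference samples absent: {missing}")
    pos = pd.Series(curve.sample_positions, index=sample_ids)
    pds = pos - pos.loc[reference_ids].mean()
    non_ref = pds.index.difference(reference_ids)
    if len(non_ref) and pds.loc[non_ref].mean() < 0:
        pds = -pds
    return PDSResult(
        pathway_name=pathway_name,
        sample_ids=sample_ids,
        pds=pds.to_numpy(),
        reference_ids=reference_ids,
    )


def pds_matrix(
    merged: MergedExpression,
    collection: GeneSetCollection,
    reference_label: str = "lean",
    status_column: str = "status",
    min_genes: int = 2,
    tol: float = 1e-6,
    max_iter: int = 50,
) -> pd.DataFrame:
    """Samples x pathways table of deregulation scores.

    For each pathway with at least ``min_genes`` genes present in the
    expression matrix: standardize each gene row (zero mean, unit variance
    across samples), fit a principal curve in the standardized pathway
    subspace and compute PDS with reference = samples carrying
    ``reference_label``.  Pathways with too few available genes are
    skipped with a logged warning.
    """
    labels = merged.metadata[status_column]
    reference_ids = list(labels.index[labels == reference_label])
    if not reference_ids:
        raise ValueError(f"no samples carry reference label {reference_label!r}")
    results: dict[str, pd.Series] = {}
    for name in sorted(collection.sets):
        genes = sorted(set(collection.sets[name]) & set(merged.gene_ids))
        if len(genes) < min_genes:
            logger.warning(
                "pathway %s skipped: %d of %d genes available (< %d)",
                name, len(genes), len(collection.sets[name]), min_genes,
            )
            continue
        sub = merged.values.loc[genes].to_numpy(dtype=float)
        sd = sub.std(axis=1, ddof=0)
        sd[sd == 0] = 1.0  # constant gene contributes nothing after centering
        Z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
        curve = fit_principal_curve(Z.T, tol=tol, max_iter=max_iter)
        res = compute_pds(curve, merged.sample_ids, reference_ids, pathway_name=name)
        results[name] = res.to_series()
    return pd.DataFrame(results, index=pd.Index(merged.sample_ids, name="sample_id"))
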