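"""Hypergeometric over-representation of signature genes in pathways.

Given a signature of ``n`` genes drawn from a universe of ``N`` genes, a
pathway with ``K`` genes in the universe and an observed overlap of ``k``
genes, the over-representation p-value is the upper hypergeometric tail
P(X >= k).  Pathway sizes are always computed after restricting the
pathway to the analysis universe (the genes available when the signature
was defined); members outside the universe are discarded.

Individual pathway p-values are reported unadjusted (a Benjamini-Hochberg
column is attached for reference but never used for selection).  The
significance of the *set* of reported pathways is assessed with an
empirical family-level p-value: draw ``n`` genes uniformly at random from
the universe many times and count how often at least the observed number
of pathways shares >= ``min_k`` genes with the draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

__all__ = [
    "GeneSetCollection",
    "EnrichmentResult",
    "FamilyResult",
    "hypergeom_overrep",
    "select_pathways",
    "family_pvalue",
]


@dataclass
class GeneSetCollection:
    """Named gene sets over a declared gene universe.

    ``sets`` maps a unique set name to its member gene ids; membership is
    restricted to ``universe`` on construction and the number of discarded
    out-of-universe members is recorded in ``n_discarded``.
    """

    sets: dict[str, frozenset[str]]
    universe: frozenset[str]
    n_discarded: int = field(default=0, compare=False)

    def __init__(self, sets: Mapping[str, Iterable[str]], universe: Iterable[str]):
        self.universe = frozenset(universe)
        restricted: dict[str, frozenset[str]] = {}
        discarded = 0
        for name, members in sets.items():
            if name in restricted:
                raise ValueError(f"duplicate set name: {name}")
            members = frozenset(members)
            kept = members & self.universe
            discarded += len(members) - len(kept)
            restricted[name] = kept
        self.sets = restricted
        self.n_discarded = discarded

    def __len__(self) -> int:
        return len(self.sets)

    def restrict_universe(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Re-restrict the collection to a (typically smaller) universe."""
        return GeneSetCollection(self.sets, frozenset(universe) & self.universe)


@dataclass
class EnrichmentResult:
    pathway_name: str
    k: int  # overlap with the signature
    K: int  # pathway size within the universe
    n: int  # signature size
    N: int  # universe size
    p_value: float
    bh_adjusted: float | None = None


@dataclass
class FamilyResult:
    observed_count: int
    null_counts: np.ndarray
    p_value: float
    n_replicates: int
    seed: int


def hypergeom_overrep(
    signature_genes: Iterable[str],
    pathway: Iterable[str],
    universe: Iterable[str],
    pathway_name: str = "",
) -> EnrichmentResult:
    """Upper-tail hypergeometric p-value for the signature/pathway overlap.

    ``p = P(X >= k)`` for ``X ~ Hypergeometric(N, K, n)`` with ``N`` the
    universe size, ``K`` the pathway size after restriction to the universe
    and ``n`` the signature size.  ``k = 0`` gives ``p = 1``.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty universe")
    sig = frozenset(signature_genes)
    if not sig <= universe:
        raise ValueError("signature genes must lie within the universe")
    path = frozenset(pathway) & universe
    k = len(sig & path)
    K = len(path)
    n = len(sig)
    N = len(universe)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return EnrichmentResult(
        pathway_name=pathway_name, k=k, K=K, n=n, N=N, p_value=min(p, 1.0)
    )


def select_pathways(
    collection: GeneSetCollection,
    signature_genes: Iterable[str],
    min_k: int = 2,
) -> list[EnrichmentResult]:
    """Over-representation results for every pathway sharing at least
    ``min_k`` genes with the signature, sorted by ascending p-value.

    A Benjamini-Hochberg adjusted p-value (computed over *all* pathways in
    the collection, not only the reported ones) is attached for reference.
    """
    if min_k < 1:
        raise ValueError("min_k must be >= 1")
    sig = frozenset(signature_genes) & collection.universe
    all_results = [
        hypergeom_overrep(sig, members, collection.universe, pathway_name=name)
        for name, members in collection.sets.items()
    ]
    pvals = np.array([r.p_value for r in all_results])
    if len(pvals):
        order = np.argsort(pvals)
        m = len(pvals)
        adj = np.empty(m)
        running = 1.0
        for rank_from_last, idx in enumerate(order[::-1]):
            rank = m - rank_from_last
            running = min(running, pvals[idx] * m / rank)
            adj[idx] = running
        for r, a in zip(all_results, adj):
            r.bh_adjusted = float(a)
    selected = [r for r in all_results if r.k >= min_k]
    selected.sort(key=lambda r: (r.p_value, r.pathway_name))
    return selected


def family_pvalue(
    collection: GeneSetCollection,
    n_genes: int,
    observed_count: int,
    min_k: int = 2,
    n_replicates: int = 10_000,
    seed: int = 0,
) -> FamilyResult:
    """Empirical family-level p-value for the reported pathway set.

    Each replicate draws ``n_genes`` uniformly without replacement from the
    universe and counts pathways with overlap >= ``min_k``;
    ``p = (1 + #{count >= observed_count}) / (1 + n_replicates)`` (add-one
    rule, so p is never exactly zero).
    """
    universe = sorted(collection.universe)
    N = len(universe)
    if n_genes > N:
        raise ValueError("n_genes exceeds universe size")
    gene_index = {g: i for i, g in enumerate(universe)}
    # indicator matrix: pathways x genes
    names = sorted(collection.sets)
    member = np.zeros((len(names), N), dtype=bool)
    for row, name in enumerate(names):
        for g in collection.sets[name]:
            member[row, gene_index[g]] = True
    rng = np.random.default_rng(seed)
    counts = np.empty(n_replicates, dtype=int)
    for r in range(n_replicates):
        draw = rng.choice(N, size=n_genes, replace=False)
        counts[r] = int((member[:, draw].sum(axis=1) >= min_k).sum())
    p = (1 + int((counts >= observed_count).sum())) / (1 + n_replicates)
    return FamilyResult(
        observed_count=observed_count,
        null_counts=counts,
        p_value=p,
        n_replicates=n_replicates,
        seed=seed,
    )
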