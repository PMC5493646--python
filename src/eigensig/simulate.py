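"""Synthetic multi-batch expression data with planted structure.

The generator emulates the situation the merging method is built for:
``K`` batches over a shared gene universe, an additive per-(batch, gene)
offset that dominates raw between-batch correlation, a small planted set
of phenotype-associated genes, and clinical covariates (BMI, fasting
glucose and insulin) derived from the same latent phenotype axis.

Model, per gene g in batch b and sample j::

    X[g, j] = mu_g + delta[b, g] + d_g * m_g * (effect_size / 2) * t_j
              + eps[g, j]

* ``mu_g`` -- baseline log2 mean, drawn once per gene and shared across
  batches so gene identity survives merging;
* ``delta[b, g] ~ N(0, batch_shift_scale^2)`` -- the batch effect;
* ``t_j`` -- the latent phenotype ``z_j ~ N(0, 1)`` rescaled by
  ``1 / E[z | z > 0]`` so that thresholding at the median gives an
  obese-minus-lean group mean difference of exactly ``effect_size * m_g``;
* ``d_g in {-1, +1}`` -- planted direction (up or down in obese);
* ``m_g`` -- per-gene effect multiplier, linearly decaying from
  ``1 + effect_spread`` to ``1 - effect_spread`` over the planted genes
  (mean 1), mimicking the decaying coefficient profile of real
  transcriptomic signatures;
* ``eps ~ N(0, noise_sd^2)`` -- residual log2 noise.

Lean/obese labels threshold the latent phenotype at its within-batch
median (balanced groups per batch); BMI is an affine map of the latent
phenotype onto the 18-45 range plus ``bmi_noise_sd`` noise; fasting
plasma glucose (mg/dL) and insulin (uU/mL) are independent noisy affine
maps of the same latent axis.  Gender is independent of the planted
effect by default; ``n_group_genes``/``group_effect_size`` can plant
gender-*specific* phenotype genes (half of them carry the phenotype
effect in females only, half in males only) to probe the specificity
test's power against genuinely gender-dependent signatures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .batch import ExpressionBatch
from .enrichment import GeneSetCollection

__all__ = ["SimConfig", "SyntheticTruth", "generate_batches", "generate_pathways"]

# E[z | z > 0] for standard normal; scaling t = z / _HALF_NORMAL_MEAN makes
# the top-vs-bottom-half group mean difference of t equal to 2.
_HALF_NORMAL_MEAN = float(np.sqrt(2.0 / np.pi))


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults describe a four-batch cohort of 20 samples each over 500
    genes, with 20 planted phenotype genes shifted by 2 log2 units
    (obese minus lean, on average over the planted set), batch offsets of
    scale 3 dominating the biology, and residual noise of 0.5 log2 units.
    """

    n_batches: int = 4
    genes_per_batch: int = 500
    samples_per_batch: Sequence[int] = (20, 20, 20, 20)
    n_planted_genes: int = 20
    effect_size: float = 2.0
    batch_shift_scale: float = 3.0
    noise_sd: float = 0.5
    bmi_noise_sd: float = 2.0
    gender_balance: float = 0.5
    seed: int = 0
    #: relative spread of per-gene effect multipliers (0 = flat profile)
    effect_spread: float = 0.5
    #: optional gender-specific planted genes (off by default: the score
    #: under study is gender-independent)
    n_group_genes: int = 0
    group_effect_size: float = 0.0

    def __post_init__(self) -> None:
        if self.n_batches < 1 or self.genes_per_batch < 1:
            raise ValueError("counts must be >= 1")
        if len(self.samples_per_batch) != self.n_batches:
            raise ValueError(
                f"samples_per_batch has length {len(self.samples_per_batch)}, "
                f"expected n_batches={self.n_batches}"
            )
        if any(n < 1 for n in self.samples_per_batch):
            raise ValueError("every batch needs at least one sample")
        if not 0 <= self.n_planted_genes <= self.genes_per_batch:
            raise ValueError("n_planted_genes must be within the gene universe")
        for name in ("effect_size", "batch_shift_scale", "noise_sd", "bmi_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.gender_balance <= 1:
            raise ValueError("gender_balance must be in [0, 1]")
        if not 0 <= self.effect_spread < 1:
            raise ValueError("effect_spread must be in [0, 1)")


@dataclass
class SyntheticTruth:
    """Ground truth behind one generated cohort."""

    planted_genes: frozenset[str]
    planted_directions: dict[str, int]  # +1 up in obese, -1 down
    latent_phenotype: pd.Series  # per sample
    batch_offsets: pd.DataFrame  # batches x genes
    group_genes: frozenset[str] = field(default_factory=frozenset)
    baseline: pd.Series | None = None  # shared per-gene log2 means


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def generate_batches(config: SimConfig) -> tuple[list[ExpressionBatch], SyntheticTruth]:
    """Generate the multi-batch cohort described by ``config``.

    All randomness flows from ``config.seed`` through a single generator;
    two calls with the same config produce identical output.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.genes_per_batch)
    n_genes = config.genes_per_batch

    baseline = rng.normal(7.0, 1.0, size=n_genes)  # shared log2 baselines
    planted_idx = rng.choice(n_genes, size=config.n_planted_genes, replace=False)
    directions = rng.choice([-1, 1], size=config.n_planted_genes)
    if config.n_planted_genes > 1:
        multipliers = np.linspace(
            1 + config.effect_spread, 1 - config.effect_spread, config.n_planted_genes
        )
    else:
        multipliers = np.ones(config.n_planted_genes)

    remaining = np.setdiff1d(np.arange(n_genes), planted_idx)
    group_idx = rng.choice(
        remaining, size=min(config.n_group_genes, remaining.size), replace=False
    )
    group_dirs = rng.choice([-1, 1], size=group_idx.size)

    offsets = rng.normal(0.0, config.batch_shift_scale, size=(config.n_batches, n_genes))

    # latent phenotype drawn up front so BMI can use one global affine map
    z_per_batch = [
        rng.normal(0.0, 1.0, size=n) for n in config.samples_per_batch
    ]
    z_all = np.concatenate(z_per_batch)
    z_lo, z_hi = z_all.min(), z_all.max()

    batches: list[ExpressionBatch] = []
    latent_all: list[pd.Series] = []
    for b, n_samples in enumerate(config.samples_per_batch):
        sample_ids = [f"B{b + 1}S{j + 1:02d}" for j in range(n_samples)]
        z = z_per_batch[b]
        t = z / _HALF_NORMAL_MEAN
        obese = z > np.median(z)
        gender = np.where(
            rng.random(n_samples) < config.gender_balance, "female", "male"
        )

        X = np.tile(baseline[:, None], (1, n_samples))
        X += offsets[b][:, None]
        X[planted_idx] += (
            directions[:, None] * multipliers[:, None] * (config.effect_size / 2.0) * t
        )
        if group_idx.size:
            # first half of the group genes respond to the phenotype in
            # females only, second half in males only; effect magnitudes
            # decay like the main planted profile
            half = group_idx.size // 2
            female = (gender == "female").astype(float)
            active = np.vstack(
                [np.tile(female, (half, 1)),
                 np.tile(1.0 - female, (group_idx.size - half, 1))]
            )
            gmult = np.concatenate([
                np.linspace(1 + config.effect_spread, 1 - config.effect_spread, half)
                if half > 1 else np.ones(half),
                np.linspace(
                    1 + config.effect_spread, 1 - config.effect_spread,
                    group_idx.size - half,
                )
                if group_idx.size - half > 1 else np.ones(group_idx.size - half),
            ])
            X[group_idx] += (
                group_dirs[:, None] * gmult[:, None]
                * (config.group_effect_size / 2.0) * t * active
            )
        X += rng.normal(0.0, config.noise_sd, size=X.shape)

        bmi = _affine_to_range(z, 18.0, 45.0, lo_in=z_lo, hi_in=z_hi) + rng.normal(
            0.0, config.bmi_noise_sd, size=n_samples
        )
        fpg = 85.0 + 10.0 * z + rng.normal(0.0, 6.0, size=n_samples)
        fpi = 10.0 + 4.0 * z + rng.normal(0.0, 2.5, size=n_samples)

        metadata = pd.DataFrame(
            {
                "batch": f"batch{b + 1}",
                "status": np.where(obese, "obese", "lean"),
                "bmi": bmi,
                "gender": gender,
                "fpg": fpg,
                "fpi": fpi,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
        batches.append(
            ExpressionBatch(
                values=pd.DataFrame(X, index=genes, columns=sample_ids),
                metadata=metadata,
            )
        )
        latent_all.append(pd.Series(z, index=sample_ids))

    gene_arr = np.asarray(genes)
    truth = SyntheticTruth(
        planted_genes=frozenset(gene_arr[planted_idx]),
        planted_directions={
            gene_arr[i]: int(d) for i, d in zip(planted_idx, directions)
        },
        latent_phenotype=pd.concat(latent_all),
        batch_offsets=pd.DataFrame(
            offsets,
            index=[f"batch{b + 1}" for b in range(config.n_batches)],
            columns=genes,
        ),
        group_genes=frozenset(gene_arr[group_idx]),
        baseline=pd.Series(baseline, index=genes),
    )
    return batches, truth


def _affine_to_range(
    z: np.ndarray, lo: float, hi: float, lo_in: float, hi_in: float
) -> np.ndarray:
    span = hi_in - lo_in
    if span == 0:
        return np.full_like(z, (lo + hi) / 2.0)
    return lo + (hi - lo) * (z - lo_in) / span


def generate_pathways(
    universe: Sequence[str],
    n_sets: int,
    size_range: tuple[int, int],
    planted_set: Sequence[str],
    n_enriched: int,
    enriched_overlap: int,
    seed: int = 0,
) -> GeneSetCollection:
    """Synthetic pathway collection with a known number of enriched sets.

    Exactly ``n_enriched`` sets each contain ``enriched_overlap`` genes from
    ``planted_set`` (the rest of their members drawn from outside it); the
    remaining ``n_sets - n_enriched`` sets are drawn uniformly from the
    whole universe.
    """
    universe = list(universe)
    planted = [g for g in planted_set if g in set(universe)]
    if len(planted) != len(set(planted_set)):
        raise ValueError("planted_set must be a subset of the universe")
    lo, hi = size_range
    if not 1 <= lo <= hi <= len(universe):
        raise ValueError("size_range must satisfy 1 <= lo <= hi <= |universe|")
    if enriched_overlap > len(planted):
        raise ValueError("enriched_overlap exceeds planted-set size")
    if n_enriched > 0 and enriched_overlap > lo:
        raise ValueError("enriched_overlap exceeds the minimum set size")
    if n_enriched > n_sets:
        raise ValueError("n_enriched exceeds n_sets")

    rng = np.random.default_rng(seed)
    non_planted = [g for g in universe if g not in set(planted)]
    sets: dict[str, frozenset[str]] = {}
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        if i < n_enriched:
            core = rng.choice(planted, size=enriched_overlap, replace=False)
            rest = rng.choice(non_planted, size=size - enriched_overlap, replace=False)
            members = frozenset(core) | frozenset(rest)
            name = f"enriched_{i + 1:03d}"
        else:
            members = frozenset(rng.choice(universe, size=size, replace=False))
            name = f"random_{i + 1:03d}"
        sets[name] = members
    return GeneSetCollection(sets, universe)
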