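"""End-to-end pipeline: simulate (optional) -> two-step merge -> signature
-> scores -> regressions -> enrichment -> pathway deregulation scores.

`run_pipeline` ties the library stages together from a single
:class:`PipelineConfig` (constructible in code or from a YAML file),
writes every artifact to a run directory, and records a manifest with the
seeds and stage summaries so a run can be reproduced bit-exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import yaml

from . import io as eio
from .association import score_regression
from .batch import ExpressionBatch, two_step_merge
from .enrichment import GeneSetCollection, family_pvalue, select_pathways
from .pds import pds_matrix
from .signature import (
    compute_score,
    first_pc_coefficients,
    null_rank_profile,
    select_signature,
)
from .simulate import SimConfig, generate_batches, generate_pathways

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs.

    Either point ``expression_paths``/``metadata_paths``/``gmt_path`` at
    files on disk, or set ``simulate`` to generate the cohort (and a
    pathway collection) in memory.
    """

    out_dir: str | Path = "eigensig_run"
    expression_paths: Sequence[str] = ()
    metadata_paths: Sequence[str] = ()
    gmt_path: str | None = None
    simulate: SimConfig | None = None
    sigma_threshold: float = 5.0
    null_replicates: int = 1000
    bootstrap_replicates: int = 1000
    family_replicates: int = 10_000
    min_overlap: int = 2
    seed: int = 0
    status_column: str = "status"
    reference_label: str = "lean"
    covariate_columns: Sequence[str] = ("bmi",)

    def __post_init__(self) -> None:
        for name in ("null_replicates", "bootstrap_replicates", "family_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if len(self.expression_paths) != len(self.metadata_paths):
            raise ValueError("need one metadata path per expression path")
        if self.simulate is None and not self.expression_paths:
            raise ValueError("provide input batches or a simulation config")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw: dict[str, Any] = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        if sim is not None:
            sim = SimConfig(**sim)
        return cls(simulate=sim, **raw)


@dataclass
class PipelineResult:
    merged: Any
    report: Any
    signature: Any
    scores: Any
    regressions: dict[str, Any]
    enrichment: list
    family: Any
    pds: Any
    manifest: dict = field(default_factory=dict)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"seed": config.seed, "stages": {}}

    if config.simulate is not None:
        batches, truth = generate_batches(config.simulate)
        eio.write_truth(truth, out / "truth.txt")
        for i, b in enumerate(batches, start=1):
            eio.write_batch(b, out / f"batch{i}_expression.tsv", out / f"batch{i}_metadata.tsv")
        collection = generate_pathways(
            universe=list(batches[0].gene_ids),
            n_sets=50,
            size_range=(10, 40),
            planted_set=sorted(truth.planted_genes),
            n_enriched=16,
            enriched_overlap=2,
            seed=config.seed,
        )
        eio.write_gmt(collection, out / "pathways.gmt")
    else:
        batches = [
            eio.read_batch(e, m)
            for e, m in zip(config.expression_paths, config.metadata_paths)
        ]
        collection = eio.read_gmt(config.gmt_path) if config.gmt_path else None

    merged, report = two_step_merge(batches, status_column=config.status_column)
    eio.write_expression_tsv(merged.values, out / "merged_expression.tsv")
    eio.write_filter_report(report, out / "filter_report.json")
    manifest["stages"]["merge"] = report.to_dict()

    coeffs = first_pc_coefficients(merged, status_column=config.status_column)
    profile = null_rank_profile(
        len(coeffs), n_replicates=config.null_replicates, seed=config.seed
    )
    signature = select_signature(coeffs, profile, sigma=config.sigma_threshold)
    eio.write_signature_tsv(signature, out / "signature.tsv")
    manifest["stages"]["signature"] = {
        "n_selected": signature.n_selected,
        "universe_size": signature.universe_size,
        "selection_pvalue": signature.selection_pvalue,
    }

    scores = compute_score(signature, merged)
    eio.write_scores_tsv(scores, out / "scores.tsv")

    regressions: dict[str, Any] = {}
    for col in config.covariate_columns:
        if col not in merged.metadata.columns:
            logger.warning("covariate %r absent from metadata; skipped", col)
            continue
        reg = score_regression(
            scores,
            merged.metadata[col].reindex(scores.sample_ids),
            n_boot=config.bootstrap_replicates,
            seed=config.seed,
        )
        regressions[col] = reg
        manifest["stages"][f"regression_{col}"] = {
            "slope": reg.slope,
            "pearson_r": reg.pearson_r,
            "p_value": reg.p_value,
            "n_samples": reg.n_samples,
        }

    enrichment_results: list = []
    family = None
    pds_table = None
    if collection is not None:
        collection = collection.restrict_universe(merged.gene_ids)
        enrichment_results = select_pathways(
            collection, signature.selected_genes, min_k=config.min_overlap
        )
        rows = [
            {
                "pathway": r.pathway_name,
                "k": r.k,
                "K": r.K,
                "p_value": r.p_value,
                "bh_adjusted": r.bh_adjusted,
            }
            for r in enrichment_results
        ]
        import pandas as pd

        pd.DataFrame(rows).to_csv(out / "enrichment.tsv", sep="\t", index=False)
        family = family_pvalue(
            collection,
            n_genes=signature.n_selected,
            observed_count=len(enrichment_results),
            min_k=config.min_overlap,
            n_replicates=config.family_replicates,
            seed=config.seed,
        )
        manifest["stages"]["enrichment"] = {
            "n_pathways": len(enrichment_results),
            "family_p": family.p_value,
        }

        selected = GeneSetCollection(
            {r.pathway_name: collection.sets[r.pathway_name] for r in enrichment_results},
            collection.universe,
        )
        if len(selected):
            pds_table = pds_matrix(
                merged,
                selected,
                reference_label=config.reference_label,
                status_column=config.status_column,
            )
            pds_table.to_csv(out / "pds.tsv", sep="\t")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=_jsonable)
    return PipelineResult(
        merged=merged,
        report=report,
        signature=signature,
        scores=scores,
        regressions=regressions,
        enrichment=enrichment_results,
        family=family,
        pds=pds_table,
        manifest=manifest,
    )


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
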