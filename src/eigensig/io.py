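"""Readers and writers for the plain-text formats the pipeline uses.

Expression matrices travel as TSV with genes as rows (first column =
gene id) and samples as columns (header row = sample ids); sample
metadata as TSV keyed by ``sample_id``; gene sets in GMT (tab-separated:
name, description, member ids); reports as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .batch import ExpressionBatch, FilterReport, MergedExpression
from .enrichment import GeneSetCollection
from .signature import ScoreVector, Signature
from .simulate import SyntheticTruth

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_metadata_tsv",
    "write_metadata_tsv",
    "read_batch",
    "write_batch",
    "read_gmt",
    "write_gmt",
    "write_signature_tsv",
    "read_signature_tsv",
    "write_scores_tsv",
    "write_filter_report",
    "write_truth",
]


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Genes x samples expression table from TSV."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed expression TSV {path}: {exc}") from exc
    if df.empty:
        raise ValueError(f"empty expression TSV: {path}")
    df.index.name = "gene_id"
    return df.astype(float)


def write_expression_tsv(values: pd.DataFrame, path: str | Path) -> None:
    values.to_csv(path, sep="\t", index_label="gene_id")


def read_metadata_tsv(path: str | Path, required: tuple[str, ...] = ("batch", "status")) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col="sample_id")
    missing = [c for c in required if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata {path} missing columns: {missing}")
    return meta


def write_metadata_tsv(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, sep="\t", index_label="sample_id")


def read_batch(expression_path: str | Path, metadata_path: str | Path) -> ExpressionBatch:
    values = read_expression_tsv(expression_path)
    metadata = read_metadata_tsv(metadata_path)
    return ExpressionBatch(values=values, metadata=metadata.loc[values.columns])


def write_batch(batch: ExpressionBatch, expression_path: str | Path, metadata_path: str | Path) -> None:
    write_expression_tsv(batch.values, expression_path)
    write_metadata_tsv(batch.metadata, metadata_path)


def read_gmt(path: str | Path, universe=None) -> GeneSetCollection:
    """GMT gene-set file.  When ``universe`` is None it defaults to the
    union of all set members."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f">=1 member (got {len(fields)} fields)"
                )
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = [g for g in fields[2:] if g]
    if universe is None:
        universe = set().union(*sets.values()) if sets else set()
    return GeneSetCollection(sets, universe)


def write_gmt(collection: GeneSetCollection, path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{description}\t{members}\n")


def write_signature_tsv(signature: Signature, path: str | Path) -> None:
    signature.to_frame().to_csv(path, sep="\t", index=False)


def read_signature_tsv(path: str | Path, sigma: float = 5.0, universe_size: int | None = None) -> Signature:
    from scipy import stats

    df = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "coefficient"):
        if col not in df.columns:
            raise ValueError(f"signature TSV {path} missing column {col!r}")
    return Signature(
        gene_ids=list(df["gene_id"]),
        coefficients=df["coefficient"].to_numpy(dtype=float),
        n_selected=len(df),
        sigma_threshold=sigma,
        selection_pvalue=float(2 * stats.norm.sf(sigma)),
        universe_size=universe_size if universe_size is not None else len(df),
    )


def write_scores_tsv(scores: ScoreVector, path: str | Path) -> None:
    scores.to_series().rename_axis("sample_id").to_csv(path, sep="\t")


def write_filter_report(report: FilterReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    """Ground truth as a plain-text key-value file."""
    with open(path, "w") as fh:
        fh.write("planted_genes\t" + ",".join(sorted(truth.planted_genes)) + "\n")
        fh.write(
            "planted_directions\t"
            + ",".join(f"{g}:{d:+d}" for g, d in sorted(truth.planted_directions.items()))
            + "\n"
        )
        fh.write(
            "latent_phenotype\t"
            + ",".join(f"{s}:{v:.6g}" for s, v in truth.latent_phenotype.items())
            + "\n"
        )
        if truth.group_genes:
            fh.write("group_genes\t" + ",".join(sorted(truth.group_genes)) + "\n")
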