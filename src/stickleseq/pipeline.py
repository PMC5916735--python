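"""End-to-end orchestration: counts -> DE -> MDS -> clustering -> enrichment."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import (
    CountMatrix, GeneAnnotation, InputError,
    read_bed, read_counts, read_group_file, write_bed, write_results,
)
from .expression import DEResult, cpm, de_analysis, mds_leading_logfc, tmm_factors
from .islands import enrichment_from_sets
from .spatial import cluster_all_chromosomes
from . import synthetic

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Flat configuration for one pipeline run.

    In synthetic mode the annotation/counts/islands are generated from
    the built-in study-regime defaults (scaled to ``synthetic_genes``
    genes); in real-data mode the three paths must exist.
    """

    out_dir: str = "stickleseq_out"
    counts: str | None = None
    annotation: str | None = None
    islands: str | None = None
    groups: str | None = None          # group file path (sample<TAB>group)
    synthetic: bool = False
    synthetic_genes: int = 1_000
    synthetic_islands: int = 20
    synthetic_island_length: int = 100_000
    fdr: float = 0.05
    dispersion: str = "auto"           # "auto" or a float as string
    t_test: str = "welch"              # welch | pooled
    n_perm: int = 1_000
    mds_top_n: int = 500
    seed: int = 1

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Read a flat ``key = value`` config file; kwargs take precedence."""
        fields = {f.name: f for f in dataclasses.fields(cls)}
        values: dict = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise InputError(f"{path}: line {lineno}: expected 'key = value'")
                key, raw = (s.strip() for s in line.split("=", 1))
                if key not in fields:
                    raise InputError(f"{path}: line {lineno}: unknown key {key!r}")
                values[key] = _coerce(raw, fields[key].type)
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)


def _coerce(raw: str, typ) -> object:
    typ = str(typ)
    if "bool" in typ:
        return raw.lower() in ("1", "true", "yes")
    if "int" in typ:
        return int(raw)
    if "float" in typ:
        return float(raw)
    if raw.lower() in ("none", ""):
        return None
    return raw


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, write all outputs + a manifest; returns the manifest.

    Outputs under ``out_dir``: ``results_de.tsv``, ``mds.tsv``,
    ``clustering.tsv``, ``enrichment.tsv`` (when islands are available),
    synthetic inputs when generated, and ``manifest.json``.  A rerun
    with the same config and seed is bit-identical.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "stickleseq",
        "version": __version__,
        "config": dataclasses.asdict(config),
        "stages": {},
    }

    # ----- inputs ---------------------------------------------------------
    truth = None
    if config.synthetic:
        gspec = synthetic.scaled_genome_spec(config.synthetic_genes, seed=config.seed)
        annotation = synthetic.simulate_annotation(gspec)
        islands = None
        if config.synthetic_islands > 0:
            islands, _ = synthetic.simulate_islands(
                annotation, config.synthetic_islands, config.synthetic_island_length,
                seed=config.seed + 1,
                chromosome_lengths=dict(
                    zip(gspec.chromosome_names, gspec.chromosome_lengths)
                ),
            )
        espec = dataclasses.replace(
            synthetic.ExpressionSpec(), seed=config.seed + 2
        )
        matrix, truth = synthetic.simulate_counts(annotation, espec, islands)
        write_bed(annotation, out / "annotation.bed")
        if islands is not None:
            write_bed(islands, out / "islands.bed")
        matrix.counts.rename_axis("gene_id").to_csv(out / "counts.tsv", sep="\t")
        synthetic.write_truth(truth, out / "truth.tsv")
    else:
        if not config.counts or not config.annotation or not config.groups:
            raise InputError("real-data mode needs --counts, --annotation and --groups")
        group_map = read_group_file(config.groups)
        matrix = read_counts(config.counts, group_map)
        annotation = read_bed(config.annotation)
        islands = read_bed(config.islands) if config.islands else None

    genes_in = len(matrix.gene_ids)

    # ----- differential expression ---------------------------------------
    factors = tmm_factors(matrix)
    logger.info("library sizes: %s", matrix.library_size.to_dict())
    logger.info("TMM factors: %s", factors.factors.round(4).to_dict())
    dispersion = "auto" if config.dispersion == "auto" else float(config.dispersion)
    de = de_analysis(matrix, fdr_threshold=config.fdr, dispersion=dispersion)
    write_results(de.table, out / "results_de.tsv", columns=DEResult.COLUMNS)
    genes_tested = int(de.table["testable"].sum())
    logger.info(
        "estimated dispersion %.4f; %d DE genes (%d up, %d down) at FDR %g",
        de.dispersion, de.n_de, de.n_up, de.n_down, config.fdr,
    )
    manifest["stages"]["de"] = {
        "genes_in": genes_in,
        "genes_tested": genes_tested,
        "genes_filtered": genes_in - genes_tested,
        "dispersion": de.dispersion,
        "n_de": de.n_de, "n_up": de.n_up, "n_down": de.n_down,
        "tmm_factors": factors.factors.round(6).to_dict(),
    }
    if truth is not None:
        planted = set(truth.loc[truth["is_de"], "gene_id"])
        detected = de.de_gene_ids()
        manifest["stages"]["de"]["planted_de"] = len(planted)
        manifest["stages"]["de"]["detected_planted"] = len(planted & detected)

    # ----- MDS ------------------------------------------------------------
    logcpm = cpm(matrix, log=True, norm_factors=factors)
    coords = mds_leading_logfc(logcpm, top_n=config.mds_top_n)
    coords.rename_axis("sample").reset_index().to_csv(out / "mds.tsv", sep="\t", index=False)
    manifest["stages"]["mds"] = {"samples": list(coords.index), "dims": coords.shape[1]}

    # ----- chromosomal clustering ----------------------------------------
    de_ids = de.de_gene_ids()
    clustering = cluster_all_chromosomes(
        annotation, de_ids, test=config.t_test,
        n_perm=config.n_perm, seed=config.seed + 3,
    )
    write_results(clustering, out / "clustering.tsv")
    manifest["stages"]["clustering"] = {
        "chromosomes_tested": int(clustering["pvalue"].notna().sum()),
        "chromosomes_total": len(clustering),
    }

    # ----- island enrichment ----------------------------------------------
    if islands is not None and len(islands) > 0:
        enrich = enrichment_from_sets(annotation, islands, de_ids)
        write_results(pd.DataFrame([enrich.as_row()]), out / "enrichment.tsv")
        manifest["stages"]["enrichment"] = enrich.as_row()
        logger.info(
            "island enrichment: k=%d observed vs lambda=%.2f expected (P=%.3g)",
            enrich.k_observed, enrich.lambda_expected, enrich.pvalue,
        )
    else:
        logger.info("no islands supplied; enrichment stage skipped")
        manifest["stages"]["enrichment"] = None

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
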