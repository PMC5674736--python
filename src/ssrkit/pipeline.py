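"""End-to-end orchestration: detect → regions → summaries → divergence tree.

A :class:`PipelineConfig` names the inputs (one FASTA per genome, optional
GFF3 annotation per genome, optional taxonomy TSV) and the stage parameters.
:func:`run_pipeline` writes the full artifact set — locus table, region
table, cohort summary, distance matrix, Newick tree and a run log — into the
output directory.  Identical config and inputs give byte-identical outputs;
the log therefore records parameters and per-stage counts but no timestamps.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as sio
from .detect import DetectionParams, find_all_ssrs
from .divergence import (
    build_profile,
    canonical_feature_space,
    length_feature_space,
    pairwise_matrix,
    upgma,
    write_newick,
)
from .regions import build_gene_models, tabulate_regions, CATEGORIES
from .stats import cohort_table, summarize_genome

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    fasta_paths: list[str]
    gff3_paths: dict[str, str] = field(default_factory=dict)  # genome_id -> path
    taxonomy_path: str | None = None
    out_dir: str = "ssrkit_out"
    detection: DetectionParams = field(default_factory=DetectionParams)
    perfection_scheme: str = "any_mismatch"
    feature_space: str = "length"  # "length" or "canonical"
    feature_k: int = 2             # used when feature_space == "canonical"
    pseudocount: float = 0.5
    rng_seed: int = 0

    def validate(self) -> None:
        if not self.fasta_paths:
            raise ValueError("at least one FASTA input required")
        for p in self.fasta_paths:
            if not os.path.exists(p):
                raise FileNotFoundError(p)
        for p in self.gff3_paths.values():
            if not os.path.exists(p):
                raise FileNotFoundError(p)
        if self.taxonomy_path and not os.path.exists(self.taxonomy_path):
            raise FileNotFoundError(self.taxonomy_path)
        if self.feature_space not in ("length", "canonical"):
            raise ValueError("feature_space must be 'length' or 'canonical'")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")


def load_config(path: str | os.PathLike, **overrides) -> PipelineConfig:
    """Read a YAML key-value config; keyword overrides win over file values."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    det_keys = {f.name for f in DetectionParams.__dataclass_fields__.values()}
    det = {k: data.pop(k) for k in list(data) if k in det_keys}
    cfg = PipelineConfig(**data)
    if det:
        cfg.detection = DetectionParams(**det)
    return cfg


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Run every stage; return a name → path map of written artifacts."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = ["# ssrkit run log"]
    log_lines.append(f"detection_params: {config.detection}")
    log_lines.append(f"perfection_scheme: {config.perfection_scheme}")
    log_lines.append(
        f"feature_space: {config.feature_space} (k={config.feature_k}) "
        f"pseudocount={config.pseudocount}"
    )
    log_lines.append(f"rng_seed: {config.rng_seed}")

    taxonomy = (
        sio.read_taxonomy(config.taxonomy_path) if config.taxonomy_path else None
    )

    all_loci = []
    summaries = []
    profiles = []
    region_rows = []
    space = (
        length_feature_space()
        if config.feature_space == "length"
        else canonical_feature_space(config.feature_k)
    )
    for fasta in sorted(config.fasta_paths):
        genome_id = Path(fasta).stem
        records = sio.read_fasta(fasta)
        loci = []
        for rec in records:
            loci.extend(find_all_ssrs(rec, config.detection))
        all_loci.extend(loci)
        summaries.append(summarize_genome(records, loci, genome_id=genome_id))
        profiles.append(
            build_profile(loci, space, config.pseudocount, genome_id=genome_id)
        )
        log_lines.append(f"genome {genome_id}: {len(records)} sequence(s), {len(loci)} loci")

        gff3 = config.gff3_paths.get(genome_id)
        if gff3:
            models = build_gene_models(gff3)
            counts = tabulate_regions(loci, models)
            region_rows.append({"genome_id": genome_id, **counts})
        else:
            logger.warning(
                "no GFF3 for genome %s; region stage skipped", genome_id
            )
            log_lines.append(f"genome {genome_id}: region stage skipped (no GFF3)")

    artifacts: dict[str, str] = {}

    locus_path = out / "loci.tsv"
    sio.write_locus_table(all_loci, locus_path)
    artifacts["loci"] = str(locus_path)
    log_lines.append(f"total loci: {len(all_loci)}")

    if region_rows:
        import pandas as pd

        region_path = out / "regions.tsv"
        pd.DataFrame(
            region_rows, columns=["genome_id", *CATEGORIES, "total"]
        ).to_csv(region_path, sep="\t", index=False)
        artifacts["regions"] = str(region_path)

    summary_path = out / "summary.tsv"
    table = cohort_table(summaries)
    if taxonomy is not None:
        table = table.merge(taxonomy, on="genome_id", how="left")
    table.to_csv(summary_path, sep="\t", index=False, float_format="%.10g")
    artifacts["summary"] = str(summary_path)

    if len(profiles) >= 2:
        dm = pairwise_matrix(profiles)
        dm_path = out / "distances.tsv"
        sio.write_distance_matrix(dm, dm_path)
        artifacts["distances"] = str(dm_path)
        tree = upgma(dm)
        tree_path = out / "tree.nwk"
        tree_path.write_text(write_newick(tree) + "\n")
        artifacts["tree"] = str(tree_path)
        log_lines.append(f"tree leaves: {len(tree.leaf_names())}")
    else:
        log_lines.append("tree stage skipped (need >= 2 genomes)")

    log_path = out / "run_log.txt"
    log_path.write_text("\n".join(log_lines) + "\n")
    artifacts["log"] = str(log_path)
    return artifacts
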