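"""End-to-end orchestration: create and update runs, output bundle, manifest.

The create path is: orient -> dereplicate -> denoise (FL-ASVs) ->
[optional: 99% OTU clustering + chimera screen (FL-OTUs)] -> backbone
top-hit search -> taxonomy trimming -> type-strain species calls -> rank
clustering -> placeholder naming -> merge -> conflict resolution ->
database writers + novelty report + *de novo* census.

The update path denoises only the new reads, drops exact duplicates of
existing FL-ASVs, appends survivors with the next canonical numbers, and
re-runs the taxonomy on the combined ordered list. Prefix stability of the
greedy clustering guarantees that every pre-existing placeholder name is
unchanged — an update is equivalent to a create over the combined input.

Everything is single-threaded and deterministic: rerunning the same config
produces bit-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import __version__
from .io_formats import (
    BackboneRecord,
    read_backbone_fasta,
    read_fasta,
    write_cluster_tsv,
    write_fasta,
    write_provenance_tsv,
    write_qiime_db,
    write_sintax_db,
    write_taxonomy_tsv,
)
from .records import (
    DenoiseParams,
    Hit,
    RankThresholds,
    SeqRecord,
    TaxProfile,
    flasv_number,
)
from .seqcore import (
    AlignScoring,
    DEFAULT_SCORING,
    chimera_screen,
    cluster_otus_99,
    dereplicate,
    denoise,
    orient,
)
from .taxonomy_engine import (
    TypeStrain,
    assign_all,
    check_tree,
    denovo_census,
    novelty_report,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and parameters of a pipeline run."""

    input_fasta: str
    backbone_fasta: str
    typestrain_fasta: str
    outdir: str
    mode: str = "create"
    existing_flasvs: str | None = None  # required in update mode
    thresholds: RankThresholds = field(default_factory=RankThresholds)
    denoise_params: DenoiseParams = field(default_factory=DenoiseParams)
    chimera_margin: float = 1.0
    include_otus: bool = False
    backbone_release: str = "unspecified"
    seed: int = 1


@dataclass
class RunResult:
    """In-memory output bundle of a create or update run."""

    flasvs: list[SeqRecord]
    profiles: dict[str, TaxProfile]
    hits: dict[str, Hit]
    cluster_sets: Mapping
    novelty: object  # DataFrame
    census: object  # DataFrame
    otus: list[SeqRecord]
    chimeras: list[SeqRecord]
    stage_counts: dict[str, int]


def _read_typestrains(path: str) -> list[TypeStrain]:
    """Type-strain FASTA: headers are ``>ACCESSION Organism name ...``."""
    strains: list[TypeStrain] = []
    from Bio import SeqIO

    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.description.split(None, 1)
        if len(parts) < 2:
            raise ValueError(f"type strain {rec.id!r} lacks an organism name")
        strains.append(
            TypeStrain(
                accession=parts[0],
                seq=SeqRecord(id=parts[0], seq=str(rec.seq)).seq,
                organism=parts[1].strip(),
            )
        )
    return strains


def write_typestrain_fasta(strains: Sequence[TypeStrain], path) -> None:
    with open(path, "w") as fh:
        for ts in strains:
            fh.write(f">{ts.accession} {ts.organism}\n{ts.seq}\n")


def build_database(
    pool: Sequence[SeqRecord],
    backbone: Sequence[BackboneRecord],
    typestrains: Sequence[TypeStrain],
    thresholds: RankThresholds = RankThresholds(),
    denoise_params: DenoiseParams = DenoiseParams(),
    include_otus: bool = False,
    chimera_margin: float = 1.0,
    existing_flasvs: Sequence[SeqRecord] | None = None,
    scoring: AlignScoring = DEFAULT_SCORING,
) -> RunResult:
    """Functional core of a create (or, with ``existing_flasvs``, update) run."""
    stage_counts = {"input": len(pool)}
    backbone_seqs = [SeqRecord(id=b.accession, seq=b.seq) for b in backbone]
    oriented = orient(pool, backbone_seqs) if pool else []
    stage_counts["oriented"] = len(oriented)
    uniques = dereplicate(oriented)
    stage_counts["uniques"] = len(uniques)
    new_flasvs = denoise(uniques, denoise_params)
    stage_counts["denoised"] = len(new_flasvs)

    if existing_flasvs:
        existing = list(existing_flasvs)
        nums = [flasv_number(r.id) for r in existing]
        if nums != list(range(1, len(existing) + 1)):
            raise ValueError("existing FL-ASVs must be numbered FLASV1..n contiguously")
        known = {r.seq for r in existing}
        survivors = [r for r in new_flasvs if r.seq not in known]
        dropped = len(new_flasvs) - len(survivors)
        if dropped:
            logger.info("update: dropped %d exact duplicates of existing FL-ASVs", dropped)
        flasvs = existing + [
            r.with_id(f"FLASV{len(existing) + i}") for i, r in enumerate(survivors, start=1)
        ]
    else:
        flasvs = new_flasvs
    stage_counts["flasvs"] = len(flasvs)

    otus: list[SeqRecord] = []
    chimeras: list[SeqRecord] = []
    if include_otus and uniques and flasvs:
        candidates = cluster_otus_99(uniques)
        stage_counts["otu_candidates"] = len(candidates)
        otus, chimeras = chimera_screen(
            candidates, flasvs, divergence_margin=chimera_margin, scoring=scoring
        )
        stage_counts["otus"] = len(otus)
        stage_counts["chimeras"] = len(chimeras)

    profiles, hits, cluster_sets = assign_all(
        flasvs, backbone, typestrains, thresholds, scoring
    )
    problems = check_tree(profiles)
    if problems:  # resolve_conflicts guarantees this never triggers
        raise AssertionError(f"taxonomy is not a tree after conflict resolution: {problems}")
    novelty = novelty_report(flasvs, backbone, thresholds, hits=hits)
    census = denovo_census(profiles)
    return RunResult(
        flasvs=flasvs,
        profiles=profiles,
        hits=hits,
        cluster_sets=cluster_sets,
        novelty=novelty,
        census=census,
        otus=otus,
        chimeras=chimeras,
        stage_counts=stage_counts,
    )


def _write_bundle(result: RunResult, config: RunConfig) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(result.flasvs, outdir / "flasvs.fasta", write_size=True)
    rows = [
        (rec.id, result.profiles[rec.id], result.hits[rec.id].identity if rec.id in result.hits else None)
        for rec in result.flasvs
    ]
    write_taxonomy_tsv(rows, outdir / "taxonomy.tsv")
    write_provenance_tsv(
        [(rec.id, result.profiles[rec.id]) for rec in result.flasvs],
        outdir / "provenance.tsv",
    )
    db_records = [(rec, result.profiles[rec.id]) for rec in result.flasvs]
    write_sintax_db(db_records, outdir / "flasvs.sintax.fasta")
    write_qiime_db(db_records, outdir / "flasvs.qiime.fasta", outdir / "flasvs.qiime.tax")
    write_cluster_tsv(dict(result.cluster_sets), outdir / "clusters.tsv")
    result.novelty.to_csv(outdir / "novelty.tsv", sep="\t", index=False)
    result.census.to_csv(outdir / "census.tsv", sep="\t", index=False)
    if result.otus:
        write_fasta(result.otus, outdir / "flotus.fasta", write_size=True)
    manifest = {
        "autotax_version": __version__,
        "mode": config.mode,
        "seed": config.seed,
        "backbone_release": config.backbone_release,
        "thresholds": dict(config.thresholds.items()),
        "denoise": {
            "minsize": config.denoise_params.minsize,
            "alpha": config.denoise_params.alpha,
        },
        "chimera_margin": config.chimera_margin,
        "include_otus": config.include_otus,
        "otu_branch": "experimental; exploratory use only" if config.include_otus else None,
        "update_denoises_new_reads_only": config.mode == "update",
        "stage_counts": result.stage_counts,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_create(config: RunConfig) -> RunResult:
    """Execute a full create run from files and write the output bundle."""
    pool = read_fasta(config.input_fasta)
    backbone = read_backbone_fasta(config.backbone_fasta)
    typestrains = _read_typestrains(config.typestrain_fasta)
    if not pool:
        logger.warning("input FASTA is empty; writing empty outputs")
    result = build_database(
        pool,
        backbone,
        typestrains,
        thresholds=config.thresholds,
        denoise_params=config.denoise_params,
        include_otus=config.include_otus,
        chimera_margin=config.chimera_margin,
    )
    _write_bundle(result, config)
    return result


def run_update(config: RunConfig) -> RunResult:
    """Execute an update run: append novel FL-ASVs, keep all existing names."""
    if not config.existing_flasvs:
        raise ValueError("update mode requires existing_flasvs")
    existing = read_fasta(config.existing_flasvs, parse_size=True)
    pool = read_fasta(config.input_fasta)
    backbone = read_backbone_fasta(config.backbone_fasta)
    typestrains = _read_typestrains(config.typestrain_fasta)
    result = build_database(
        pool,
        backbone,
        typestrains,
        thresholds=config.thresholds,
        denoise_params=config.denoise_params,
        include_otus=config.include_otus,
        chimera_margin=config.chimera_margin,
        existing_flasvs=existing,
    )
    _write_bundle(result, config)
    return result
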