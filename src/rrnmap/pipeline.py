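"""End-to-end orchestration: trim -> length filter -> map -> chimera scrub ->
block filter -> best-AS assignment -> abundance tables.

``run_reads`` is the in-memory engine; ``run_pipeline`` wraps it with file
I/O, a serialized config and a machine-readable run manifest so a run can be
reproduced byte for byte from its output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .align import AlignParams, build_index, hits_to_paf, map_reads
from .chimera import ChimeraParams, flag_reads
from .classify import (
    ClassifyParams,
    abundance_table,
    assign_reads,
    assignments_frame,
)
from .io import read_fastq
from .markers import get_marker
from .preprocess import PreprocessParams, preprocess_reads
from .refdb import ReferenceDB, load_reference_fasta

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    marker: str
    reads: str = ""
    db: str = ""
    outdir: str = ""
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    align: AlignParams = field(default_factory=AlignParams)
    chimera: ChimeraParams = field(default_factory=ChimeraParams)
    classify: ClassifyParams = field(default_factory=ClassifyParams)
    seed: int = 0
    version: str = __version__

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        raw = json.loads(text)
        return cls(
            marker=raw["marker"],
            reads=raw.get("reads", ""),
            db=raw.get("db", ""),
            outdir=raw.get("outdir", ""),
            preprocess=PreprocessParams(**{
                **raw.get("preprocess", {}),
                "length_windows": raw.get("preprocess", {}).get("length_windows"),
            }),
            align=AlignParams(**raw.get("align", {})),
            chimera=ChimeraParams(**raw.get("chimera", {})),
            classify=ClassifyParams(**raw.get("classify", {})),
            seed=raw.get("seed", 0),
            version=raw.get("version", __version__),
        )


@dataclass
class PipelineResult:
    marker: str
    assignments: list
    hits_by_read: dict
    flags: pd.DataFrame
    species_table: object
    genus_table: object
    stats: dict
    read_lengths: dict

    @property
    def assignments_df(self) -> pd.DataFrame:
        return assignments_frame(self.assignments)


def run_reads(
    reads,
    db: ReferenceDB,
    marker=None,
    preprocess_params: PreprocessParams = PreprocessParams(),
    align_params: AlignParams = AlignParams(),
    chimera_params: ChimeraParams = ChimeraParams(),
    classify_params: ClassifyParams = ClassifyParams(),
) -> PipelineResult:
    """Run the whole analysis on in-memory reads against a loaded DB."""
    marker = get_marker(marker or db.marker)
    if not reads:
        raise PipelineError("preprocess", "no reads in input")
    kept, stats = preprocess_reads(reads, marker, preprocess_params)
    logger.info("preprocess: %s", stats)
    index = build_index(db, align_params)
    hits_by_read = map_reads(index, kept, align_params)
    read_lengths = {r.read_id: len(r.sequence) for r in kept}
    flags = flag_reads(hits_by_read, read_lengths, chimera_params)
    flag_map = dict(zip(flags["read_id"], flags["status"]))
    # only chimeric/uncovered block classification; clean reads proceed
    excl = {k: v for k, v in flag_map.items() if v in ("chimeric", "uncovered")}
    assignments = assign_reads(hits_by_read, db, marker, classify_params, flags=excl)
    status_counts = (
        assignments_frame(assignments)["status"].value_counts().to_dict()
        if assignments
        else {}
    )
    stats = {**stats, "status_counts": status_counts, "n_mapped_stage_reads": len(kept)}
    species_table = abundance_table(assignments, "species")
    genus_table = abundance_table(assignments, "genus")
    return PipelineResult(
        marker=marker.name,
        assignments=assignments,
        hits_by_read=hits_by_read,
        flags=flags,
        species_table=species_table,
        genus_table=genus_table,
        stats=stats,
        read_lengths=read_lengths,
    )


def run_pipeline(config: RunConfig) -> Path:
    """File-level pipeline run; returns the output directory.

    Writes: config.json, assignments.tsv, abundance_species.tsv,
    abundance_genus.tsv, chimera_flags.tsv, hits.tsv, manifest.json.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(config.to_json())
    try:
        reads = read_fastq(config.reads)
    except Exception as exc:  # malformed input
        raise PipelineError("load-reads", str(exc)) from exc
    try:
        db = load_reference_fasta(config.db, config.marker)
    except Exception as exc:
        raise PipelineError("load-db", str(exc)) from exc
    result = run_reads(
        reads,
        db,
        config.marker,
        config.preprocess,
        config.align,
        config.chimera,
        config.classify,
    )
    all_hits = [h for hits in result.hits_by_read.values() for h in hits]
    hits_to_paf(all_hits, db, result.read_lengths).to_csv(
        outdir / "hits.tsv", sep="\t", index=False
    )
    result.assignments_df.to_csv(outdir / "assignments.tsv", sep="\t", index=False)
    result.flags.to_csv(outdir / "chimera_flags.tsv", sep="\t", index=False)
    result.species_table.rows.to_csv(
        outdir / "abundance_species.tsv", sep="\t", index=False
    )
    result.genus_table.rows.to_csv(
        outdir / "abundance_genus.tsv", sep="\t", index=False
    )
    manifest = {
        "version": config.version,
        "seed": config.seed,
        "marker": result.marker,
        "stats": result.stats,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir
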