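"""End-to-end orchestration: simulate/load -> QC -> partition -> vlincs.

A run writes all artifacts to one output directory plus a ``manifest.json``
recording parameters, seed, package version and per-stage read counts; the
manifest suffices to reproduce the run. Reruns with the same config produce
byte-identical outputs. Inputs are never mutated.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from . import __version__, io, qc
from .models import AlignedRead, TranscriptModel
from .partition import (
    AnnotationIndex,
    classify_reads,
    density_track,
    feature_expression,
    partition_summary,
)
from .simulate import SimulatedDataset, SyntheticConfig, simulate
from .stats import rank_features
from .vlinc import CallerParams, call_domains, pool_intergenic_density


@dataclass
class PipelineConfig:
    """Everything one run needs; either a synthetic config or input paths."""

    out_dir: Path
    sim: Optional[SyntheticConfig] = None
    annotation_path: Optional[Path] = None
    alignments_path: Optional[Path] = None
    chrom_sizes_path: Optional[Path] = None
    min_len: int = 25
    score_threshold: float = qc.HUMAN_THRESHOLD
    excluded_contigs: Tuple[str, ...] = qc.DEFAULT_EXCLUDED_CONTIGS
    caller: CallerParams = field(default_factory=CallerParams)
    sample_id: str = "sample"
    write_genome: bool = False

    def validate(self) -> None:
        """Fail before any computation when inputs are missing."""
        if self.sim is None:
            for name in ("annotation_path", "alignments_path", "chrom_sizes_path"):
                path = getattr(self, name)
                if path is None or not Path(path).exists():
                    raise FileNotFoundError(f"{name} missing or does not exist: {path}")


def _stage(manifest: dict, name: str, **info) -> None:
    manifest["stages"].append({"name": name, **info})


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.sim.seed if config.sim else None,
        "parameters": {
            "min_len": config.min_len,
            "score_threshold": config.score_threshold,
            "excluded_contigs": list(config.excluded_contigs),
            "caller": dataclasses.asdict(config.caller),
        },
        "stages": [],
    }

    # Stage 1: acquire inputs.
    if config.sim is not None:
        dataset = simulate(config.sim)
        transcripts = dataset.transcripts
        placements = dataset.reads.placements
        chrom_sizes = dict(config.sim.chrom_sizes)
        io.write_bed12(out / "annotation.bed12", transcripts)
        io.write_genepred(out / "annotation.genepred.tsv", transcripts)
        io.write_alignment_tsv(out / "alignments.tsv", placements)
        io.write_chrom_sizes(out / "chrom_sizes.tsv", chrom_sizes)
        dataset.reads.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        io.write_bed(out / "planted_vlincs.bed", dataset.vlincs)
        io.write_fasta(
            out / "reads.fasta",
            dataset.reads.raw_sequences,
        )
        if config.write_genome:
            io.write_fasta(out / "genome.fasta", dataset.genome)
        _stage(manifest, "simulate", n_reads=len(dataset.reads.raw_sequences))
    else:
        transcripts = _load_annotation(Path(config.annotation_path))
        placements = io.read_alignment_tsv(config.alignments_path)
        chrom_sizes = io.read_chrom_sizes(config.chrom_sizes_path)
        _stage(manifest, "load", n_placements=len(placements))

    # Stage 2: QC cascade to the informative read set.
    informative, counts = qc.run_qc(
        placements,
        min_len=config.min_len,
        threshold=config.score_threshold,
        excluded_contigs=config.excluded_contigs,
    )
    io.write_alignment_tsv(out / "informative.tsv", informative)
    _stage(manifest, "qc", **counts)

    # Stage 3: classification and partition bookkeeping.
    index = AnnotationIndex(transcripts, chrom_sizes)
    classify_reads(informative, index)
    summary = partition_summary(informative, config.sample_id)
    with open(out / "partition_summary.tsv", "w") as fh:
        fh.write("sample_id\tn_exonic\tn_intronic\tn_intergenic\tinformative\n")
        fh.write(
            f"{summary.sample_id}\t{summary.n_exonic}\t{summary.n_intronic}"
            f"\t{summary.n_intergenic}\t{summary.informative_total}\n"
        )
    _stage(
        manifest, "classify",
        n_exonic=summary.n_exonic, n_intronic=summary.n_intronic,
        n_intergenic=summary.n_intergenic,
    )

    # Stage 4: density track over all informative reads.
    track = density_track(informative, summary.informative_total, chrom_sizes)
    io.write_bedgraph(out / "density.bedgraph", track)
    _stage(manifest, "density", informative=summary.informative_total)

    # Stage 5: pooled intergenic density and vlinc calling.
    samples = {config.sample_id: (informative, summary.informative_total)}
    try:
        intergenic = pool_intergenic_density(samples, index, chrom_sizes)
        domains = call_domains(intergenic, config.caller, transcripts)
    except ValueError:
        domains = []
    io.write_bed(out / "vlincs.bed", domains)
    _stage(manifest, "call_vlinc", n_domains=len(domains))

    # Stage 6: expression and ranking over genes + called vlincs.
    features = [
        (t.transcript_id, t.chrom, t.start, t.end) for t in transcripts
    ] + [(d.domain_id, d.chrom, d.start, d.end) for d in domains]
    if features:
        expr = feature_expression(features, informative, summary.informative_total)
        expr.to_csv(out / "expression.tsv", sep="\t")
        ranks = rank_features(expr[["per_10m"]].rename(columns={"per_10m": config.sample_id}))
        ranks.to_csv(out / "ranks.tsv", sep="\t")
    _stage(manifest, "expression", n_features=len(features))

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _load_annotation(path: Path) -> List[TranscriptModel]:
    if path.suffix in (".bed12", ".bed"):
        return io.read_bed12(path)
    return io.read_genepred(path)
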