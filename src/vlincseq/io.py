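"""Readers and writers for the on-disk formats of the pipeline.

BED/BED12/bedGraph, a genePred-like TSV for transcript models, FASTA for
sequences, a simplified alignment TSV carrying the gapped tag/ref strings
(so the scoring formula stays auditable from disk), and a read-only SAM
subset for importing external alignments. Every writer round-trips
bit-exactly through its own reader. Coordinates are 0-based half-open on
disk for all BED-family formats, as the standards require; malformed lines
are reported with their line number.
"""
from __future__ import annotations

import math
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import AlignedRead, AlignmentBlock, Category, TranscriptModel, VlincDomain
from .partition import DensityTrack

PathLike = Union[str, Path]


def _fail(path: PathLike, lineno: int, message: str) -> None:
    raise ValueError(f"{path}:{lineno}: {message}")


# ---------------------------------------------------------------------------
# FASTA

def write_fasta(path: PathLike, sequences: Mapping[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: PathLike) -> Dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# BED (3-6 columns) and BED12

def write_bed(
    path: PathLike,
    intervals: Iterable[Union[Tuple[str, int, int], Tuple[str, int, int, str], VlincDomain]],
) -> None:
    with open(path, "w") as fh:
        for item in intervals:
            if isinstance(item, VlincDomain):
                fh.write(f"{item.chrom}\t{item.start}\t{item.end}\t{item.domain_id}\n")
            elif len(item) == 3:
                chrom, s, e = item
                fh.write(f"{chrom}\t{s}\t{e}\n")
            else:
                chrom, s, e, name = item
                fh.write(f"{chrom}\t{s}\t{e}\t{name}\n")


def read_bed(path: PathLike) -> List[Tuple]:
    """Parse BED3/BED4+; returns (chrom, start, end[, name]) tuples."""
    out: List[Tuple] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                _fail(path, lineno, f"expected >= 3 BED columns, got {len(fields)}")
            try:
                s, e = int(fields[1]), int(fields[2])
            except ValueError:
                _fail(path, lineno, "non-integer BED coordinates")
            if len(fields) >= 4:
                out.append((fields[0], s, e, fields[3]))
            else:
                out.append((fields[0], s, e))
    return out


def read_bed_domains(path: PathLike) -> List[VlincDomain]:
    domains = []
    for i, rec in enumerate(read_bed(path), start=1):
        name = rec[3] if len(rec) > 3 else f"vlinc_{i}"
        domains.append(VlincDomain(name, rec[0], rec[1], rec[2]))
    return domains


def write_bed12(path: PathLike, transcripts: Iterable[TranscriptModel]) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            sizes = ",".join(str(e - s) for s, e in t.exons) + ","
            rel_starts = ",".join(str(s - t.start) for s in t.exon_starts) + ","
            fh.write(
                "\t".join(
                    [
                        t.chrom, str(t.start), str(t.end), t.transcript_id, "0",
                        t.strand, str(t.start), str(t.end), "0",
                        str(len(t.exon_starts)), sizes, rel_starts,
                    ]
                )
                + "\n"
            )


def read_bed12(path: PathLike) -> List[TranscriptModel]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                _fail(path, lineno, f"expected 12 BED12 columns, got {len(fields)}")
            try:
                start, end = int(fields[1]), int(fields[2])
                n_blocks = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                rel = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError:
                _fail(path, lineno, "malformed BED12 numeric field")
            if len(sizes) != n_blocks or len(rel) != n_blocks:
                _fail(path, lineno, "block count does not match block lists")
            exon_starts = tuple(start + r for r in rel)
            exon_ends = tuple(s + sz for s, sz in zip(exon_starts, sizes))
            out.append(
                TranscriptModel(
                    transcript_id=fields[3], chrom=fields[0], strand=fields[5],
                    start=start, end=end,
                    exon_starts=exon_starts, exon_ends=exon_ends,
                )
            )
    return out


# ---------------------------------------------------------------------------
# genePred-like TSV

_GENEPRED_HEADER = [
    "name", "chrom", "strand", "txStart", "txEnd",
    "cdsStart", "cdsEnd", "exonCount", "exonStarts", "exonEnds",
]


def write_genepred(path: PathLike, transcripts: Iterable[TranscriptModel]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_GENEPRED_HEADER) + "\n")
        for t in transcripts:
            fh.write(
                "\t".join(
                    [
                        t.transcript_id, t.chrom, t.strand,
                        str(t.start), str(t.end), str(t.start), str(t.end),
                        str(len(t.exon_starts)),
                        ",".join(map(str, t.exon_starts)) + ",",
                        ",".join(map(str, t.exon_ends)) + ",",
                    ]
                )
                + "\n"
            )


def read_genepred(path: PathLike) -> List[TranscriptModel]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("name\t"):
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                _fail(path, lineno, f"expected 10 genePred columns, got {len(fields)}")
            try:
                starts = tuple(int(x) for x in fields[8].rstrip(",").split(","))
                ends = tuple(int(x) for x in fields[9].rstrip(",").split(","))
                out.append(
                    TranscriptModel(
                        transcript_id=fields[0], chrom=fields[1], strand=fields[2],
                        start=int(fields[3]), end=int(fields[4]),
                        exon_starts=starts, exon_ends=ends,
                    )
                )
            except ValueError:
                _fail(path, lineno, "malformed genePred numeric field")
    return out


# ---------------------------------------------------------------------------
# bedGraph

def write_bedgraph(path: PathLike, track: DensityTrack) -> None:
    """Emit runs of constant non-zero density; values use repr precision."""
    with open(path, "w") as fh:
        fh.write("track type=bedGraph\n")
        fh.write(f"# informative_reads={track.informative}\n")
        for chrom in sorted(track.arrays):
            arr = track.arrays[chrom]
            fh.write(f"# chrom_size {chrom} {arr.size}\n")
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            bounds = np.concatenate(([0], change, [arr.size]))
            for s, e in zip(bounds[:-1], bounds[1:]):
                v = float(arr[s])
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v!r}\n")


def read_bedgraph(
    path: PathLike,
    chrom_sizes: Optional[Mapping[str, int]] = None,
    informative: Optional[int] = None,
) -> DensityTrack:
    """Read a bedGraph back into a density track.

    Chromosome sizes and the informative count are taken from the header
    comments our writer emits, unless given explicitly.
    """
    sizes: Dict[str, int] = dict(chrom_sizes) if chrom_sizes else {}
    values: List[Tuple[str, int, int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser")):
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if parts and parts[0] == "chrom_size" and len(parts) == 3:
                    sizes.setdefault(parts[1], int(parts[2]))
                elif parts and parts[0].startswith("informative_reads="):
                    if informative is None:
                        informative = int(parts[0].split("=", 1)[1])
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                _fail(path, lineno, f"expected 4 bedGraph columns, got {len(fields)}")
            try:
                values.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
            except ValueError:
                _fail(path, lineno, "malformed bedGraph numeric field")
    if informative is None:
        raise ValueError(f"{path}: informative read count not recorded or given")
    for chrom, s, e, _ in values:
        if chrom not in sizes:
            sizes[chrom] = 0
        sizes[chrom] = max(sizes[chrom], e)
    arrays = {c: np.zeros(n, dtype=float) for c, n in sizes.items()}
    for chrom, s, e, v in values:
        arrays[chrom][s:e] = v
    return DensityTrack(arrays=arrays, informative=informative)


# ---------------------------------------------------------------------------
# Simplified alignment TSV

_ALN_HEADER = [
    "read_id", "chrom", "start", "tag_gapped", "ref_gapped",
    "n_best_placements", "category", "raw_score", "normalized_score",
]


def write_alignment_tsv(path: PathLike, reads: Iterable[AlignedRead]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_ALN_HEADER) + "\n")
        for r in reads:
            raw = "" if r.raw_score is None else str(r.raw_score)
            norm = "" if r.normalized_score is None else repr(r.normalized_score)
            fh.write(
                "\t".join(
                    [
                        r.read_id, r.chrom, str(r.start),
                        r.block.tag_gapped, r.block.ref_gapped,
                        str(r.n_best_placements), r.category.value, raw, norm,
                    ]
                )
                + "\n"
            )


def read_alignment_tsv(path: PathLike) -> List[AlignedRead]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("read_id\t"):
                continue
            fields = line.split("\t")
            if len(fields) != len(_ALN_HEADER):
                _fail(
                    path, lineno,
                    f"expected {len(_ALN_HEADER)} alignment columns, got {len(fields)}",
                )
            try:
                out.append(
                    AlignedRead(
                        read_id=fields[0], chrom=fields[1], start=int(fields[2]),
                        block=AlignmentBlock(fields[3], fields[4]),
                        n_best_placements=int(fields[5]),
                        category=Category(fields[6]),
                        raw_score=int(fields[7]) if fields[7] else None,
                        normalized_score=float(fields[8]) if fields[8] else None,
                    )
                )
            except ValueError as exc:
                _fail(path, lineno, f"malformed alignment record ({exc})")
    return out


# ---------------------------------------------------------------------------
# SAM subset (read-only import of external alignments)

def read_sam(path: PathLike) -> List[AlignedRead]:
    """Import mapped, single-end primary alignments from a SAM text file.

    Gapped tag/ref rows are rebuilt from the CIGAR string; when the MD tag
    is present the reference row carries true reference bases, otherwise
    aligned positions are taken as matches (deletion columns then show
    ``N`` for the unknown reference base).
    """
    import pysam

    out: List[AlignedRead] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            query = rec.query_sequence or ""
            try:
                ref = rec.get_reference_sequence().upper()
            except (ValueError, KeyError):
                ref = None
            tag_row: List[str] = []
            ref_row: List[str] = []
            qi = ri = 0
            for op, length in rec.cigartuples or ():
                if op in (0, 7, 8):  # M/=/X
                    seg = query[qi : qi + length]
                    tag_row.append(seg)
                    ref_row.append(ref[ri : ri + length] if ref else seg)
                    qi += length
                    ri += length
                elif op == 1:  # insertion in read
                    tag_row.append(query[qi : qi + length])
                    ref_row.append("-" * length)
                    qi += length
                elif op == 2:  # deletion from reference
                    tag_row.append("-" * length)
                    ref_row.append(ref[ri : ri + length] if ref else "N" * length)
                    ri += length
                elif op in (4, 5):  # clips: not part of the alignment block
                    if op == 4:
                        qi += length
                else:
                    raise ValueError(
                        f"unsupported CIGAR op {op} in read {rec.query_name}"
                    )
            out.append(
                AlignedRead(
                    read_id=rec.query_name,
                    chrom=rec.reference_name,
                    start=int(rec.reference_start),
                    block=AlignmentBlock("".join(tag_row), "".join(ref_row)),
                )
            )
    return out


# ---------------------------------------------------------------------------
# Flat key-value config files

def read_config(path: PathLike) -> Dict[str, str]:
    """Parse ``key = value`` lines; ``#`` comments and blanks ignored."""
    out: Dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                _fail(path, lineno, "expected 'key = value'")
            key, _, value = line.partition("=")
            out[key.strip()] = value.strip()
    return out


def write_chrom_sizes(path: PathLike, chrom_sizes: Mapping[str, int]) -> None:
    with open(path, "w") as fh:
        for chrom, size in chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def read_chrom_sizes(path: PathLike) -> Dict[str, int]:
    out: Dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                _fail(path, lineno, "expected 'chrom<TAB>size'")
            try:
                out[fields[0]] = int(fields[1])
            except ValueError:
                _fail(path, lineno, "non-integer chromosome size")
    return out
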