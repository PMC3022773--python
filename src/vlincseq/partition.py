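"""Classify informative reads against a transcript annotation.

A read is *exonic* when its aligned genomic footprint overlaps at least one
exonic base of any transcript (either strand), *intronic* when it overlaps a
transcript span but no exon, and *intergenic* otherwise. Precedence is
exon > intron > intergenic for boundary-spanning reads, which is the
conservative choice: ambiguous exonic overlap deflates, never inflates, the
un-annotated ("dark matter") fraction.

Per-base density tracks and per-feature expression are normalized to reads
per 10 million informative reads; a feature's *relative mass* is its read
count as a percentage of informative reads, a mass-fraction proxy for RNA
abundance (SMS read counts, not covered bases, estimate mass because read
lengths vary).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .models import (
    AlignedRead,
    Category,
    PartitionSummary,
    TranscriptModel,
)

NORMALIZATION_READS = 10_000_000  # "reads per 10 M informative"

FeatureDef = Tuple[str, str, int, int]  # (feature_id, chrom, start, end)


class AnnotationIndex:
    """Interval index over transcript exons and spans for classification."""

    def __init__(
        self,
        transcripts: Sequence[TranscriptModel],
        chrom_sizes: Optional[Mapping[str, int]] = None,
    ) -> None:
        self.transcripts = list(transcripts)
        self.chrom_sizes = dict(chrom_sizes) if chrom_sizes else None
        self._exons: Dict[str, IntervalTree] = {}
        self._spans: Dict[str, IntervalTree] = {}
        for t in self.transcripts:
            span_tree = self._spans.setdefault(t.chrom, IntervalTree())
            span_tree.addi(t.start, t.end)
            exon_tree = self._exons.setdefault(t.chrom, IntervalTree())
            for s, e in t.exons:
                exon_tree.addi(s, e)

    def classify(self, chrom: str, start: int, end: int) -> Category:
        if self.chrom_sizes is not None and chrom not in self.chrom_sizes:
            raise KeyError(f"read on unknown chromosome {chrom!r}")
        exons = self._exons.get(chrom)
        if exons is not None and exons.overlap(start, end):
            return Category.EXONIC
        spans = self._spans.get(chrom)
        if spans is not None and spans.overlap(start, end):
            return Category.INTRONIC
        return Category.INTERGENIC

    def gene_spans(self, chrom: str) -> List[Tuple[int, int]]:
        tree = self._spans.get(chrom)
        return sorted((i.begin, i.end) for i in tree) if tree else []


def classify_read(read: AlignedRead, index: AnnotationIndex) -> Category:
    """Category of one placed read (footprint overlap, strand-agnostic)."""
    return index.classify(read.chrom, read.start, read.end)


def classify_reads(
    reads: Iterable[AlignedRead], index: AnnotationIndex
) -> List[AlignedRead]:
    """Assign categories in place; returns the same read list."""
    out = list(reads)
    for read in out:
        read.category = classify_read(read, index)
    return out


def partition_summary(
    reads: Iterable[AlignedRead], sample_id: str = "sample"
) -> PartitionSummary:
    """Count exonic/intronic/intergenic reads; fails on an empty sample."""
    counts = {Category.EXONIC: 0, Category.INTRONIC: 0, Category.INTERGENIC: 0}
    for read in reads:
        if read.category not in counts:
            raise ValueError(
                f"read {read.read_id} has category {read.category}; classify first"
            )
        counts[read.category] += 1
    summary = PartitionSummary(
        sample_id=sample_id,
        n_exonic=counts[Category.EXONIC],
        n_intronic=counts[Category.INTRONIC],
        n_intergenic=counts[Category.INTERGENIC],
    )
    if summary.informative_total == 0:
        raise ValueError("zero informative reads; cannot summarize partition")
    return summary


@dataclass
class DensityTrack:
    """Per-chromosome per-base coverage, reads per 10 M informative.

    ``arrays`` maps chromosome -> float array of normalized depth; bases
    covered by no read are 0. ``scale`` is 1e7 / informative reads.
    """

    arrays: Dict[str, np.ndarray]
    informative: int

    @property
    def scale(self) -> float:
        return NORMALIZATION_READS / self.informative

    def total(self) -> float:
        return float(sum(a.sum() for a in self.arrays.values()))


def _raw_depth(
    reads: Iterable[AlignedRead], chrom_sizes: Mapping[str, int]
) -> Dict[str, np.ndarray]:
    """Unnormalized integer coverage depth per chromosome."""
    per_chrom: Dict[str, Tuple[List[int], List[int]]] = {
        c: ([], []) for c in chrom_sizes
    }
    for read in reads:
        if read.chrom not in per_chrom:
            raise KeyError(f"read on chromosome {read.chrom!r} missing from sizes")
        per_chrom[read.chrom][0].append(read.start)
        per_chrom[read.chrom][1].append(min(read.end, chrom_sizes[read.chrom]))
    out: Dict[str, np.ndarray] = {}
    for chrom, (starts, ends) in per_chrom.items():
        diff = np.zeros(chrom_sizes[chrom] + 1, dtype=np.int64)
        if starts:
            np.add.at(diff, np.asarray(starts), 1)
            np.add.at(diff, np.asarray(ends), -1)
        out[chrom] = np.cumsum(diff[:-1])
    return out


def density_track(
    reads: Iterable[AlignedRead],
    informative_count: int,
    chrom_sizes: Mapping[str, int],
) -> DensityTrack:
    """Coverage depth scaled to reads per 10 M informative reads."""
    if informative_count <= 0:
        raise ValueError("informative_count must be positive")
    depth = _raw_depth(reads, chrom_sizes)
    scale = NORMALIZATION_READS / informative_count
    return DensityTrack(
        arrays={c: a.astype(float) * scale for c, a in depth.items()},
        informative=informative_count,
    )


def relative_mass_pct(count: float, informative: int) -> float:
    """A feature's read count as a percentage of informative reads."""
    if informative <= 0:
        raise ValueError("informative count must be positive")
    return 100.0 * count / informative


def _feature_dict(
    features: Union[Mapping[str, Tuple[str, int, int]], Iterable[FeatureDef]],
) -> Dict[str, Tuple[str, int, int]]:
    if isinstance(features, Mapping):
        return {str(k): (c, int(s), int(e)) for k, (c, s, e) in features.items()}
    out: Dict[str, Tuple[str, int, int]] = {}
    for fid, chrom, s, e in features:
        if fid in out:
            raise ValueError(f"duplicate feature id {fid!r}")
        out[fid] = (chrom, int(s), int(e))
    return out


def feature_expression(
    features: Union[Mapping[str, Tuple[str, int, int]], Iterable[FeatureDef]],
    reads: Iterable[AlignedRead],
    informative_count: int,
) -> pd.DataFrame:
    """Raw/normalized counts and relative mass per genomic feature.

    A feature is a plain span (a transcript's exon+intron extent, or a vlinc
    interval). A read overlapping several features counts in each. Returns a
    DataFrame indexed by feature id with columns raw_count, per_10m,
    relative_mass_pct.
    """
    if informative_count <= 0:
        raise ValueError("informative_count must be positive")
    fdict = _feature_dict(features)
    trees: Dict[str, IntervalTree] = {}
    for fid, (chrom, s, e) in fdict.items():
        trees.setdefault(chrom, IntervalTree()).addi(s, e, fid)
    counts = {fid: 0 for fid in fdict}
    for read in reads:
        tree = trees.get(read.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(read.start, read.end):
            counts[hit.data] += 1
    raw = pd.Series(counts, name="raw_count", dtype=float)
    df = pd.DataFrame(
        {
            "raw_count": raw,
            "per_10m": raw * (NORMALIZATION_READS / informative_count),
            "relative_mass_pct": 100.0 * raw / informative_count,
        }
    )
    df.index.name = "feature_id"
    return df.loc[list(fdict)]


def expression_matrix(
    features: Union[Mapping[str, Tuple[str, int, int]], Iterable[FeatureDef]],
    samples: Mapping[str, Tuple[Sequence[AlignedRead], int]],
    column: str = "per_10m",
) -> pd.DataFrame:
    """Features x samples table of normalized expression.

    ``samples`` maps sample id -> (reads, informative count). A feature
    absent from a sample's reads gets 0.
    """
    cols = {}
    for sid, (reads, informative) in samples.items():
        cols[sid] = feature_expression(features, reads, informative)[column]
    return pd.DataFrame(cols)


def intron_exon_density_screen(
    transcripts: Sequence[TranscriptModel],
    reads: Sequence[AlignedRead],
    informative_count: int,
    chrom_sizes: Mapping[str, int],
    min_reads_per_10m: float = 50.0,
) -> List[str]:
    """Spliced transcripts with an intron at least as dense as their exons.

    Considers transcripts whose total (exon+intron) read count reaches
    ``min_reads_per_10m`` after normalization; flags those with >= 1 intron
    whose mean per-base coverage depth equals or exceeds the mean exonic
    depth. Intronless transcripts are skipped, not failed.
    """
    if informative_count <= 0:
        raise ValueError("informative_count must be positive")
    depth = _raw_depth(reads, chrom_sizes)
    # Per-chromosome sorted endpoints for fast span read counting.
    starts_by_chrom: Dict[str, np.ndarray] = {}
    ends_by_chrom: Dict[str, np.ndarray] = {}
    for chrom in chrom_sizes:
        rs = np.array(sorted(r.start for r in reads if r.chrom == chrom))
        re_ = np.array(sorted(r.end for r in reads if r.chrom == chrom))
        starts_by_chrom[chrom], ends_by_chrom[chrom] = rs, re_
    scale = NORMALIZATION_READS / informative_count
    flagged: List[str] = []
    for t in transcripts:
        introns = t.introns
        if not introns:
            continue
        rs = starts_by_chrom.get(t.chrom)
        if rs is None or rs.size == 0:
            continue
        # reads with start < span end minus reads ending at/before span start
        n_span = int(np.searchsorted(rs, t.end, "left")) - int(
            np.searchsorted(ends_by_chrom[t.chrom], t.start, "right")
        )
        if n_span * scale < min_reads_per_10m:
            continue
        d = depth[t.chrom]
        exon_bases = np.concatenate([d[s:e] for s, e in t.exons])
        exon_density = float(exon_bases.mean())
        for s, e in introns:
            if float(d[s:e].mean()) >= exon_density:
                flagged.append(t.transcript_id)
                break
    return flagged
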