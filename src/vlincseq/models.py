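"""Core data types shared across the pipeline.

Coordinates are 0-based half-open throughout; 1-based genome-browser
coordinates are converted only at file I/O boundaries.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Optional, Tuple


class Category(str, Enum):
    """Origin class of a placed read."""

    RIBOSOMAL = "ribosomal"
    MITOCHONDRIAL = "mitochondrial"
    EXONIC = "exonic"
    INTRONIC = "intronic"
    INTERGENIC = "intergenic"
    UNASSIGNED = "unassigned"


#: The three classes that partition the informative reads.
GENOMIC_CATEGORIES = (Category.EXONIC, Category.INTRONIC, Category.INTERGENIC)


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript with ordered, disjoint exon blocks on one chromosome."""

    transcript_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exon_starts: Tuple[int, ...]
    exon_ends: Tuple[int, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError("transcript span must be non-empty and non-negative")
        if len(self.exon_starts) != len(self.exon_ends) or not self.exon_starts:
            raise ValueError("need matching, non-empty exon block lists")
        prev_end = None
        for s, e in zip(self.exon_starts, self.exon_ends):
            if not (self.start <= s < e <= self.end):
                raise ValueError("exon block outside transcript span")
            if prev_end is not None and s < prev_end:
                raise ValueError("exon blocks must be sorted and disjoint")
            prev_end = e

    @property
    def exons(self) -> List[Tuple[int, int]]:
        return list(zip(self.exon_starts, self.exon_ends))

    @property
    def introns(self) -> List[Tuple[int, int]]:
        return [
            (e, s)
            for e, s in zip(self.exon_ends[:-1], self.exon_starts[1:])
            if s > e
        ]

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AlignmentBlock:
    """Gapped tag/reference display of one alignment.

    ``tag_gapped`` and ``ref_gapped`` have equal display length; ``-`` marks a
    gap. A gap in the tag row is a deleted reference base; a gap in the
    reference row is an inserted tag base. Both count as errors, as do
    substitutions.
    """

    tag_gapped: str
    ref_gapped: str

    def __post_init__(self) -> None:
        if len(self.tag_gapped) != len(self.ref_gapped):
            raise ValueError("tag and ref rows must have equal display length")
        if not self.tag_gapped:
            raise ValueError("empty alignment block")
        for t, r in zip(self.tag_gapped, self.ref_gapped):
            if t == "-" and r == "-":
                raise ValueError("column with gaps in both rows")

    @property
    def display_length(self) -> int:
        return len(self.tag_gapped)

    @property
    def tag_length(self) -> int:
        """Number of (ungapped) tag bases."""
        return sum(1 for c in self.tag_gapped if c != "-")

    @property
    def ref_length(self) -> int:
        """Genomic footprint of the alignment in reference bases."""
        return sum(1 for c in self.ref_gapped if c != "-")

    @property
    def n_matches(self) -> int:
        return sum(
            1
            for t, r in zip(self.tag_gapped, self.ref_gapped)
            if t == r and t != "-"
        )

    @property
    def n_errors(self) -> int:
        """Substitutions plus gaps in either row."""
        return self.display_length - self.n_matches


@dataclass
class AlignedRead:
    """A read placed on the genome with its alignment and scores."""

    read_id: str
    chrom: str
    start: int
    block: AlignmentBlock
    raw_score: Optional[int] = None
    normalized_score: Optional[float] = None
    n_best_placements: int = 1
    category: Category = Category.UNASSIGNED

    @property
    def end(self) -> int:
        """0-based half-open end of the genomic footprint."""
        return self.start + self.block.ref_length

    @property
    def tag_length(self) -> int:
        return self.block.tag_length


@dataclass(frozen=True)
class VlincDomain:
    """A called very long intergenic non-coding (vlinc) interval."""

    domain_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("empty or negative domain interval")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PartitionSummary:
    """Per-sample exonic/intronic/intergenic read bookkeeping."""

    sample_id: str
    n_exonic: int
    n_intronic: int
    n_intergenic: int

    @property
    def informative_total(self) -> int:
        return self.n_exonic + self.n_intronic + self.n_intergenic

    @property
    def fractions(self) -> Dict[Category, float]:
        total = self.informative_total
        if total == 0:
            raise ValueError("no informative reads in partition summary")
        return {
            Category.EXONIC: self.n_exonic / total,
            Category.INTRONIC: self.n_intronic / total,
            Category.INTERGENIC: self.n_intergenic / total,
        }

    @property
    def nonexonic_fraction(self) -> float:
        fr = self.fractions
        return fr[Category.INTRONIC] + fr[Category.INTERGENIC]
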