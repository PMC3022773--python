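"""Read trimming, filtering and alignment scoring for error-prone SMS reads.

Single-molecule sequencing of dA-tailed cDNA leaves two artifacts this module
handles: leading T homopolymers (a priming by-product trimmed away before
alignment) and a deletion-dominant error profile. A placed read is scored

    raw score        = 5 * n_matches - 4 * n_errors
    normalized score = raw score / tag length

where *errors* are substitutions plus gaps in either alignment row and *tag
length* is the ungapped, trimmed read length. The maximal normalized score is
5.0 (error-free). Reads are kept when the normalized score reaches the
species threshold (4.5 for the human genome, 4.3 for fly), have a unique
best placement, and do not map to ribosomal/mitochondrial sequence; the
survivors are the *informative reads* used as the normalization denominator
everywhere downstream.
"""
from __future__ import annotations

from collections import OrderedDict
from typing import Dict, Iterable, List, NamedTuple, Optional, Sequence, Tuple

from intervaltree import IntervalTree

from .models import AlignedRead, AlignmentBlock

MATCH_SCORE = 5
ERROR_PENALTY = -4

#: Stringent normalized-score thresholds per genome.
HUMAN_THRESHOLD = 4.5
FLY_THRESHOLD = 4.3

#: Contigs excluded from the informative read set by default.
DEFAULT_EXCLUDED_CONTIGS = ("rDNA", "chrM")


def trim_leading_t(sequence: str) -> str:
    """Remove the longest leading run of T homopolymer bases.

    The empty string is a legal result (an all-T read).
    """
    i = 0
    while i < len(sequence) and sequence[i] == "T":
        i += 1
    return sequence[i:]


def filter_min_length(
    reads: Dict[str, str], min_len: int = 25
) -> Dict[str, str]:
    """Keep trimmed reads of at least ``min_len`` bases (boundary included)."""
    return {rid: seq for rid, seq in reads.items() if len(seq) >= min_len}


def score_alignment(block: AlignmentBlock) -> Tuple[int, float]:
    """Score an alignment block: (raw, normalized).

    raw = 5*matches - 4*errors; normalized = raw / ungapped tag length.
    """
    tag_len = block.tag_length
    if tag_len == 0:
        raise ValueError("cannot normalize: alignment block has no tag bases")
    raw = MATCH_SCORE * block.n_matches + ERROR_PENALTY * block.n_errors
    return raw, raw / tag_len


class AlignmentResult(NamedTuple):
    block: AlignmentBlock
    ref_start: int  # offset of the alignment within the reference window


def align_read(tag: str, reference_window: str) -> AlignmentResult:
    """Best semi-global alignment of ``tag`` against ``reference_window``.

    Dynamic programming under +5 per match and -4 per substitution or gapped
    position; the whole tag is aligned while reference overhangs on either
    side are free. Deterministic tie-break prefers diagonal moves.
    """
    if not tag or not reference_window:
        raise ValueError("tag and reference window must be non-empty")
    m, n = len(tag), len(reference_window)
    # dp[i][j]: best score aligning tag[:i] with an alignment ending at ref
    # position j; row 0 is free (leading reference bases cost nothing).
    dp = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(1, m + 1):
        dp[i][0] = dp[i - 1][0] + ERROR_PENALTY
    for i in range(1, m + 1):
        ti = tag[i - 1]
        row, prev = dp[i], dp[i - 1]
        for j in range(1, n + 1):
            diag = prev[j - 1] + (
                MATCH_SCORE if ti == reference_window[j - 1] else ERROR_PENALTY
            )
            up = prev[j] + ERROR_PENALTY  # tag base against ref gap
            left = row[j - 1] + ERROR_PENALTY  # ref base against tag gap
            row[j] = max(diag, up, left)
    last = dp[m]
    j_best = max(range(n + 1), key=lambda j: (last[j], -j))
    # Traceback.
    tag_g: List[str] = []
    ref_g: List[str] = []
    i, j = m, j_best
    while i > 0:
        if j > 0:
            step = (
                MATCH_SCORE
                if tag[i - 1] == reference_window[j - 1]
                else ERROR_PENALTY
            )
            if dp[i][j] == dp[i - 1][j - 1] + step:
                tag_g.append(tag[i - 1])
                ref_g.append(reference_window[j - 1])
                i, j = i - 1, j - 1
                continue
        if dp[i][j] == dp[i - 1][j] + ERROR_PENALTY:
            tag_g.append(tag[i - 1])
            ref_g.append("-")
            i -= 1
            continue
        tag_g.append("-")
        ref_g.append(reference_window[j - 1])
        j -= 1
    block = AlignmentBlock("".join(reversed(tag_g)), "".join(reversed(ref_g)))
    return AlignmentResult(block, j)


def score_reads(reads: Iterable[AlignedRead]) -> List[AlignedRead]:
    """Fill in raw and normalized scores on each placement record."""
    out = list(reads)
    for read in out:
        read.raw_score, read.normalized_score = score_alignment(read.block)
    return out


def filter_by_normalized_score(
    reads: Iterable[AlignedRead], threshold: float = HUMAN_THRESHOLD
) -> List[AlignedRead]:
    """Keep placements whose normalized score reaches ``threshold``."""
    kept = []
    for read in reads:
        if read.normalized_score is None:
            raise ValueError(f"read {read.read_id} has no score; run score_reads")
        if read.normalized_score >= threshold:
            kept.append(read)
    return kept


def unique_best_filter(placements: Iterable[AlignedRead]) -> List[AlignedRead]:
    """Keep reads with exactly one placement attaining their best score.

    Ties drop the read entirely. The retained record carries the winning
    placement and the number of candidate placements that attained the best
    score. Input order of first appearance per read is preserved.
    """
    by_read: "OrderedDict[str, List[AlignedRead]]" = OrderedDict()
    for p in placements:
        if p.normalized_score is None:
            raise ValueError(f"read {p.read_id} has no score; run score_reads")
        by_read.setdefault(p.read_id, []).append(p)
    kept: List[AlignedRead] = []
    for rid, plist in by_read.items():
        best = max(p.normalized_score for p in plist)
        winners = [p for p in plist if p.normalized_score == best]
        if len(winners) == 1:
            winners[0].n_best_placements = 1
            kept.append(winners[0])
    return kept


def exclude_rrna_mt(
    reads: Iterable[AlignedRead],
    excluded_contigs: Sequence[str] = DEFAULT_EXCLUDED_CONTIGS,
    rrna_intervals: Optional[Iterable[Tuple[str, int, int]]] = None,
    known_chroms: Optional[Sequence[str]] = None,
) -> List[AlignedRead]:
    """Remove ribosomal/mitochondrial reads; survivors are informative.

    A read is dropped if it lies on an excluded contig or overlaps a masked
    rRNA repeat interval by at least 1 bp. ``known_chroms``, when given,
    validates the contig names of the interval list.
    """
    excluded = set(excluded_contigs)
    trees: Dict[str, IntervalTree] = {}
    for chrom, s, e in rrna_intervals or ():
        if known_chroms is not None and chrom not in known_chroms:
            raise ValueError(f"rRNA interval on unknown contig {chrom!r}")
        trees.setdefault(chrom, IntervalTree()).addi(s, e)
    kept = []
    for read in reads:
        if read.chrom in excluded:
            continue
        tree = trees.get(read.chrom)
        if tree is not None and tree.overlap(read.start, read.end):
            continue
        kept.append(read)
    return kept


def run_qc(
    placements: Iterable[AlignedRead],
    min_len: int = 25,
    threshold: float = HUMAN_THRESHOLD,
    excluded_contigs: Sequence[str] = DEFAULT_EXCLUDED_CONTIGS,
    rrna_intervals: Optional[Iterable[Tuple[str, int, int]]] = None,
    known_chroms: Optional[Sequence[str]] = None,
) -> Tuple[List[AlignedRead], Dict[str, int]]:
    """Run the placement-level QC cascade and log per-stage read counts.

    Stage order is fixed: minimum trimmed length -> scoring -> normalized
    score threshold -> unique best placement -> ribosomal/mitochondrial
    exclusion. Each stage only removes or annotates reads. The returned
    counts are per distinct read (not per placement).
    """
    placements = list(placements)

    def n_reads(ps: Iterable[AlignedRead]) -> int:
        return len({p.read_id for p in ps})

    counts = {"input": n_reads(placements)}
    placements = [p for p in placements if p.tag_length >= min_len]
    counts["min_length"] = n_reads(placements)
    placements = score_reads(placements)
    placements = filter_by_normalized_score(placements, threshold)
    counts["score_threshold"] = n_reads(placements)
    reads = unique_best_filter(placements)
    counts["unique_best"] = len(reads)
    reads = exclude_rrna_mt(reads, excluded_contigs, rrna_intervals, known_chroms)
    counts["informative"] = len(reads)
    return reads, counts


def prepare_raw_reads(
    sequences: Dict[str, str], min_len: int = 25
) -> Tuple[Dict[str, str], Dict[str, int]]:
    """Trim leading-T artifacts and drop too-short reads (FASTA entry point)."""
    trimmed = {rid: trim_leading_t(seq) for rid, seq in sequences.items()}
    kept = filter_min_length(trimmed, min_len)
    return kept, {"input": len(sequences), "min_length": len(kept)}
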