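"""Independent reference implementations used only for cross-checking.

These deliberately avoid the code paths they validate: the alignment
oracle enumerates alignments recursively instead of filling a DP matrix,
coverage is counted base by base, ranks come from an explicit sort, and
the chi-square statistic is the textbook sum over cells.
"""
from __future__ import annotations

from functools import lru_cache
from typing import Dict, Iterable, List, Sequence, Tuple

MATCH, PENALTY = 5, -4


def best_alignment_score(tag: str, ref: str) -> int:
    """Exhaustive optimum over all alignments of the whole tag.

    Reference overhangs on either side are free; every tag base is either
    matched/mismatched against a reference base, or placed against a gap.
    """

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> int:
        if i == len(tag):
            return 0  # remaining reference bases are free overhang
        best = rec(i + 1, j) + PENALTY  # tag base against a gap
        if j < len(ref):
            step = MATCH if tag[i] == ref[j] else PENALTY
            best = max(best, rec(i + 1, j + 1) + step)
            best = max(best, rec(i, j + 1) + PENALTY)  # deleted ref base
        return best

    result = max(rec(0, j) for j in range(len(ref) + 1))
    rec.cache_clear()
    return result


def per_base_coverage(
    reads: Iterable[Tuple[str, int, int]], chrom_sizes: Dict[str, int]
) -> Dict[str, List[int]]:
    """Count, for every single base, how many reads cover it."""
    cov = {c: [0] * n for c, n in chrom_sizes.items()}
    for chrom, start, end in reads:
        for pos in range(start, min(end, chrom_sizes[chrom])):
            cov[chrom][pos] += 1
    return cov


def descending_min_ranks(values: Sequence[float]) -> List[int]:
    """Competition ranks by explicit sorting: 1 + count of strictly larger."""
    return [1 + sum(1 for w in values if w > v) for v in values]


def chi_square_statistic(table: Sequence[Sequence[float]]) -> float:
    """Textbook chi-square: sum over cells of (O - E)^2 / E."""
    rows = [sum(r) for r in table]
    cols = [sum(c) for c in zip(*table)]
    total = sum(rows)
    stat = 0.0
    for i, row in enumerate(table):
        for j, obs in enumerate(row):
            expected = rows[i] * cols[j] / total
            stat += (obs - expected) ** 2 / expected
    return stat


def interval_membership_counts(
    set_a: Sequence[Tuple[str, int, int]],
    set_b: Sequence[Tuple[str, int, int]],
    universe: Sequence[Tuple[str, int, int]],
) -> Tuple[int, int, int, int]:
    """(both, A only, B only, neither) by checking every universe base."""
    both = a_only = b_only = neither = 0
    for chrom, us, ue in universe:
        for pos in range(us, ue):
            in_a = any(c == chrom and s <= pos < e for c, s, e in set_a)
            in_b = any(c == chrom and s <= pos < e for c, s, e in set_b)
            if in_a and in_b:
                both += 1
            elif in_a:
                a_only += 1
            elif in_b:
                b_only += 1
            else:
                neither += 1
    return both, a_only, b_only, neither
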