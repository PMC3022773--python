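"""Small interval-set algebra on 0-based half-open (start, end) tuples.

These helpers back domain clipping and the base-pair overlap bookkeeping of
the comparative statistics. All functions accept any iterable of (start, end)
pairs and return sorted, merged, non-overlapping interval lists.
"""
from __future__ import annotations

from typing import Iterable, List, Tuple

Interval = Tuple[int, int]


def merge(intervals: Iterable[Interval]) -> List[Interval]:
    """Sort and merge overlapping or touching intervals; drop empty ones."""
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    out: List[List[int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def intersect(a: Iterable[Interval], b: Iterable[Interval]) -> List[Interval]:
    """Intersection of two interval sets."""
    am, bm = merge(a), merge(b)
    out: List[Interval] = []
    i = j = 0
    while i < len(am) and j < len(bm):
        s = max(am[i][0], bm[j][0])
        e = min(am[i][1], bm[j][1])
        if s < e:
            out.append((s, e))
        if am[i][1] < bm[j][1]:
            i += 1
        else:
            j += 1
    return out


def subtract(a: Iterable[Interval], b: Iterable[Interval]) -> List[Interval]:
    """Parts of ``a`` not covered by ``b``."""
    am, bm = merge(a), merge(b)
    out: List[Interval] = []
    j = 0
    for s, e in am:
        cur = s
        while j < len(bm) and bm[j][1] <= cur:
            j += 1
        k = j
        while k < len(bm) and bm[k][0] < e:
            bs, be = bm[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if cur >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def total_bp(intervals: Iterable[Interval]) -> int:
    """Total base pairs covered (after merging)."""
    return sum(e - s for s, e in merge(intervals))


def overlap_bp(a: Interval, b: Interval) -> int:
    """Overlap in bp between two single intervals."""
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))
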