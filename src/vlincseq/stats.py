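"""Downstream comparative statistics on expression tables and interval sets.

Covers abundance ranking of features (vlincs alone or pooled with annotated
genes), tumour/normal fold ratios of per-group maximal normalized counts,
Spearman correlation matrices with a top-two-quartile expression filter,
interval-set overlap with a chi-square test on base-pair contingency, and
median length comparison between interval sets.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import intervals as iv

Interval3 = Tuple[str, int, int]  # (chrom, start, end)

TUMOUR = "tumour"
NORMAL = "normal"


@dataclass
class SampleGroupDesign:
    """Sample -> group (tumour|normal) with optional patient and cohort.

    ``patients`` marks matched pairs (same patient id => same individual).
    ``cohorts`` distinguishes tumour types (e.g. a sarcoma panel vs. a
    leukaemia line) so tumour-vs-other-tumour pairs are identifiable.
    """

    groups: Dict[str, str]
    patients: Dict[str, str] = field(default_factory=dict)
    cohorts: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sample, g in self.groups.items():
            if g not in (TUMOUR, NORMAL):
                raise ValueError(f"sample {sample!r} has unknown group {g!r}")

    @property
    def tumour_samples(self) -> List[str]:
        return [s for s, g in self.groups.items() if g == TUMOUR]

    @property
    def normal_samples(self) -> List[str]:
        return [s for s, g in self.groups.items() if g == NORMAL]

    def pair_class(self, a: str, b: str) -> str:
        ga, gb = self.groups[a], self.groups[b]
        if {ga, gb} == {TUMOUR, NORMAL}:
            return "tumour_vs_normal"
        if ga == gb == NORMAL:
            return "normal_vs_normal"
        pa, pb = self.patients.get(a), self.patients.get(b)
        if pa is not None and pa == pb:
            return "same_patient"
        ca, cb = self.cohorts.get(a), self.cohorts.get(b)
        if ca is not None and cb is not None and ca != cb:
            return "tumour_vs_other_tumour"
        return "different_patient"


def rank_features(expression: pd.DataFrame) -> pd.DataFrame:
    """Descending competition ranks per sample (column).

    Ties share the best rank and the next rank skips ([10, 5, 5, 1] ->
    [1, 2, 2, 4]). Missing values are treated as 0 expression. To rank a
    vlinc within a combined vlinc+gene universe, concatenate both tables
    first.
    """
    filled = expression.fillna(0.0)
    ranks = {
        col: sps.rankdata(-filled[col].to_numpy(), method="min")
        for col in filled.columns
    }
    return pd.DataFrame(ranks, index=filled.index, dtype=int)


def group_rank_summary(
    ranks: pd.DataFrame, samples: Sequence[str]
) -> pd.DataFrame:
    """Average and minimum rank per feature over a named sample group."""
    sub = ranks[list(samples)]
    return pd.DataFrame(
        {"average_rank": sub.mean(axis=1), "minimum_rank": sub.min(axis=1)}
    )


@dataclass
class FoldRatioSummary:
    median_ratio: float
    n_tumour_2x: int
    n_tumour_10x: int
    n_normal_2x: int
    n_normal_10x: int
    t_statistic: float
    p_value: float


def max_count_fold_ratio(
    expression: pd.DataFrame,
    design: SampleGroupDesign,
    pseudocount: float = 1.0,
) -> Tuple[pd.Series, FoldRatioSummary]:
    """Tumour/normal fold ratio of per-group maximal counts, per feature.

    ratio = (max over tumour samples + pseudocount) /
            (max over normal samples + pseudocount)

    The pseudocount (default one normalized read) guards features absent in
    the normals. The summary reports the median ratio, counts of features
    at >= 2x and >= 10x in each direction, and a one-sample t-test of the
    log2 ratios against 0 (ratios are strictly positive and skewed, so the
    test is taken on the log scale).
    """
    tumours = [s for s in design.tumour_samples if s in expression.columns]
    normals = [s for s in design.normal_samples if s in expression.columns]
    if not tumours or not normals:
        raise ValueError("need at least one tumour and one normal sample")
    tmax = expression[tumours].fillna(0.0).max(axis=1)
    nmax = expression[normals].fillna(0.0).max(axis=1)
    ratios = (tmax + pseudocount) / (nmax + pseudocount)
    log2r = np.log2(ratios.to_numpy())
    if len(ratios) > 1 and np.ptp(log2r) > 0:
        t_stat, p = sps.ttest_1samp(log2r, 0.0)
    else:
        t_stat, p = float("nan"), float("nan")
    summary = FoldRatioSummary(
        median_ratio=float(ratios.median()),
        n_tumour_2x=int((ratios >= 2).sum()),
        n_tumour_10x=int((ratios >= 10).sum()),
        n_normal_2x=int((ratios <= 0.5).sum()),
        n_normal_10x=int((ratios <= 0.1).sum()),
        t_statistic=float(t_stat),
        p_value=float(p),
    )
    return ratios, summary


def quartile_filter(expression: pd.DataFrame) -> pd.DataFrame:
    """Keep the top two quartiles (Q1-Q2) of features by summed expression.

    Features are sorted by expression summed across samples and the top
    half retained; this avoids inflating correlations with features not
    expressed in any sample.
    """
    totals = expression.fillna(0.0).sum(axis=1)
    keep = totals.sort_values(ascending=False, kind="stable").index[
        : int(np.ceil(len(totals) / 2))
    ]
    return expression.loc[expression.index.intersection(keep, sort=False)]


def spearman_matrix(
    expression: pd.DataFrame, apply_quartile_filter: bool = True
) -> pd.DataFrame:
    """All pairwise Spearman correlations between samples (columns).

    A constant expression vector makes the correlation undefined for its
    pairs; those entries are reported as NaN, never as 0.
    """
    if expression.shape[1] < 2:
        raise ValueError("need at least two samples")
    table = quartile_filter(expression) if apply_quartile_filter else expression
    return table.fillna(0.0).corr(method="spearman")


def group_average_correlations(
    corr: pd.DataFrame, design: SampleGroupDesign
) -> Dict[str, float]:
    """Mean correlation per pair class over the off-diagonal pairs."""
    sums: Dict[str, List[float]] = {}
    samples = list(corr.columns)
    for i, a in enumerate(samples):
        for b in samples[i + 1 :]:
            value = corr.loc[a, b]
            if pd.isna(value):
                continue
            sums.setdefault(design.pair_class(a, b), []).append(float(value))
    return {k: float(np.mean(v)) for k, v in sums.items()}


@dataclass
class OverlapResult:
    """Interval-set overlap with base-pair chi-square significance."""

    n_a: int
    n_b: int
    n_a_overlapping: int
    n_b_overlapping: int
    bp_overlap: int
    contingency: np.ndarray  # [[both, A only], [B only, neither]] in bp
    chi_square: float
    p_value: float


def interval_overlap(
    set_a: Sequence[Interval3],
    set_b: Sequence[Interval3],
    universe: Sequence[Interval3],
    min_overlap_bp: int = 1,
) -> OverlapResult:
    """Overlap between two interval sets over a stated universe.

    Counts intervals of A overlapping *some single* interval of B by at
    least ``min_overlap_bp`` (and vice versa), the total overlapping base
    pairs, and a chi-square test (no continuity correction) on the 2x2
    base-pair contingency of membership in A x membership in B over the
    universe (e.g. the intergenic space).
    """
    if min_overlap_bp < 0:
        raise ValueError("min_overlap_bp must be >= 0")

    def by_chrom(ivs: Sequence[Interval3]) -> Dict[str, List[Tuple[int, int]]]:
        d: Dict[str, List[Tuple[int, int]]] = {}
        for chrom, s, e in ivs:
            d.setdefault(chrom, []).append((int(s), int(e)))
        return d

    a_by, b_by, u_by = by_chrom(set_a), by_chrom(set_b), by_chrom(universe)

    def count_overlapping(
        xs: Sequence[Interval3], other: Dict[str, List[Tuple[int, int]]]
    ) -> int:
        n = 0
        for chrom, s, e in xs:
            hits = other.get(chrom, [])
            if any(iv.overlap_bp((s, e), o) >= max(min_overlap_bp, 1) for o in hits):
                n += 1
        return n

    n_a_over = count_overlapping(set_a, b_by)
    n_b_over = count_overlapping(set_b, a_by)

    both = a_only = b_only = neither = 0
    chroms = set(a_by) | set(b_by) | set(u_by)
    bp_overlap = 0
    for chrom in chroms:
        a = iv.merge(a_by.get(chrom, []))
        b = iv.merge(b_by.get(chrom, []))
        bp_overlap += iv.total_bp(iv.intersect(a, b))
        u = iv.merge(u_by.get(chrom, []))
        if not u:
            continue
        a_u = iv.intersect(a, u)
        b_u = iv.intersect(b, u)
        ab = iv.total_bp(iv.intersect(a_u, b_u))
        both += ab
        a_only += iv.total_bp(a_u) - ab
        b_only += iv.total_bp(b_u) - ab
        neither += iv.total_bp(u) - iv.total_bp(iv.merge(a_u + b_u))
    table = np.array([[both, a_only], [b_only, neither]], dtype=float)
    if table.sum() == 0 or (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        chi2, p = float("nan"), float("nan")
    else:
        chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return OverlapResult(
        n_a=len(set_a),
        n_b=len(set_b),
        n_a_overlapping=n_a_over,
        n_b_overlapping=n_b_over,
        bp_overlap=int(bp_overlap),
        contingency=table,
        chi_square=float(chi2),
        p_value=float(p),
    )


@dataclass
class MedianLengthResult:
    median_a: float
    median_b: float
    t_statistic: float
    p_value: float


def median_length_compare(
    set_a: Sequence[Interval3], set_b: Sequence[Interval3]
) -> MedianLengthResult:
    """Median interval lengths and a Welch t-test on the raw lengths."""
    if not set_a or not set_b:
        raise ValueError("both interval sets must be non-empty")
    la = np.array([e - s for _, s, e in set_a], dtype=float)
    lb = np.array([e - s for _, s, e in set_b], dtype=float)
    t, p = sps.ttest_ind(la, lb, equal_var=False)
    return MedianLengthResult(
        median_a=float(np.median(la)),
        median_b=float(np.median(lb)),
        t_statistic=float(t),
        p_value=float(p),
    )
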