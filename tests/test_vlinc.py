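"""Domain calling: thresholding, merging, clipping and recovery."""
from __future__ import annotations

import numpy as np
import pytest

from vlincseq.models import AlignedRead, AlignmentBlock, Category, TranscriptModel
from vlincseq.partition import DensityTrack
from vlincseq.vlinc import (
    CallerParams,
    call_domains,
    nearest_rank_percentile,
    pool_intergenic_density,
    recover_planted,
)
from vlincseq.partition import AnnotationIndex

from oracles import per_base_coverage


def _track(arr, informative=10_000_000, chrom="chr1"):
    return DensityTrack({chrom: np.asarray(arr, dtype=float)}, informative)


def _block_track(blocks, size=200_000):
    """Density 1.0 inside the given (start, end) blocks, 0 elsewhere."""
    arr = np.zeros(size)
    for s, e in blocks:
        arr[s:e] = 1.0
    return _track(arr)


class TestCallerParams:
    @pytest.mark.parametrize(
        "kwargs", [dict(threshold_percentile=0), dict(threshold_percentile=100),
                   dict(max_gap=-1), dict(min_run=0)]
    )
    def test_invalid_params(self, kwargs):
        with pytest.raises(ValueError):
            CallerParams(**kwargs)


class TestCallDomains:
    def test_single_long_block(self):
        track = _block_track([(10_000, 70_000)])
        domains = call_domains(track)
        assert len(domains) == 1
        d = domains[0]
        assert (d.start, d.end) == (10_000, 70_000)
        assert d.domain_id == "vlinc_1"

    def test_gap_at_most_max_gap_merges(self):
        track = _block_track([(10_000, 40_000), (44_000, 74_000)])
        domains = call_domains(track)
        assert len(domains) == 1
        assert (domains[0].start, domains[0].end) == (10_000, 74_000)

    def test_gap_above_max_gap_does_not_merge(self):
        track = _block_track([(10_000, 40_000), (46_000, 76_000)])
        assert call_domains(track) == []  # two sub-min_run fragments

    def test_below_min_run_dropped(self):
        assert call_domains(_block_track([(10_000, 50_000)])) == []

    def test_empty_chromosome_yields_nothing(self):
        assert call_domains(_track(np.zeros(1_000))) == []

    def test_percentile_excludes_weak_background(self):
        """Background at depth 1 falls below an 80th percentile set by a
        dominant depth-5 domain, so only the domain is called."""
        arr = np.zeros(400_000)
        arr[0:300_000:3_000] = 1.0  # scattered weak bases
        arr[100_000: 400_000] = 5.0
        domains = call_domains(_track(arr))
        assert len(domains) == 1
        assert (domains[0].start, domains[0].end) == (100_000, 400_000)

    def test_clipping_against_gene_spans(self):
        gene = TranscriptModel("g", "chr1", "+", 60_000, 80_000, (60_000,), (80_000,))
        track = _block_track([(0, 55_000), (58_000, 190_000)])
        domains = call_domains(track, transcripts=[gene])
        spans = [(d.start, d.end) for d in domains]
        assert spans == [(0, 60_000), (80_000, 190_000)]

    def test_clipped_fragment_below_min_run_dropped(self):
        gene = TranscriptModel("g", "chr1", "+", 40_000, 80_000, (40_000,), (80_000,))
        track = _block_track([(0, 130_000)])
        domains = call_domains(track, transcripts=[gene])
        # 0-40k fragment < min_run disappears; 80k-130k survives
        assert [(d.start, d.end) for d in domains] == [(80_000, 130_000)]

    def test_deterministic(self):
        track = _block_track([(10_000, 70_000), (90_000, 160_000)])
        assert call_domains(track) == call_domains(track)


class TestNearestRankPercentile:
    def test_small_sample(self):
        values = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert nearest_rank_percentile(values, 80) == 4.0
        assert nearest_rank_percentile(values, 20) == 1.0

    def test_empty_fails(self):
        with pytest.raises(ValueError):
            nearest_rank_percentile(np.array([]), 80)


class TestMonotonicity:
    def _random_track(self, rng):
        arr = np.zeros(300_000)
        for _ in range(rng.integers(3, 12)):
            s = int(rng.integers(0, 280_000))
            arr[s : s + int(rng.integers(1_000, 60_000))] += rng.integers(1, 4)
        return _track(arr)

    def test_invariants_and_monotonicity_under_fuzz(self):
        rng = np.random.default_rng(123)
        for _ in range(25):
            track = self._random_track(rng)
            base = CallerParams(max_gap=5_000, min_run=30_000)
            domains = call_domains(track, base)
            for d in domains:
                assert d.length >= base.min_run
            ordered = sorted((d.start, d.end) for d in domains)
            for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
                assert s2 - e1 > base.max_gap  # disjoint beyond the merge gap
            # raising min_run never adds domains
            stricter = call_domains(track, CallerParams(max_gap=5_000, min_run=60_000))
            assert len(stricter) <= len(domains)
            assert {(d.start, d.end) for d in stricter} <= {
                (d.start, d.end) for d in domains
            }
            # raising max_gap never splits: domain count cannot grow
            wider = call_domains(track, CallerParams(max_gap=20_000, min_run=30_000))
            for d in domains:
                assert any(w.start <= d.start and d.end <= w.end for w in wider)


class TestPooling:
    def _reads(self, starts, chrom="chr1"):
        out = []
        for i, s in enumerate(starts):
            seq = "A" * 30
            r = AlignedRead(f"r{i}_{s}", chrom, s, AlignmentBlock(seq, seq))
            out.append(r)
        return out

    def test_identical_samples_double_depth(self, toy_transcripts):
        index = AnnotationIndex(toy_transcripts, {"chr1": 100_000})
        sizes = {"chr1": 100_000}
        one = pool_intergenic_density(
            {"a": (self._reads([50_000]), 10)}, index, sizes
        )
        two = pool_intergenic_density(
            {"a": (self._reads([50_000]), 10), "b": (self._reads([50_000]), 10)},
            index,
            sizes,
        )
        # raw depth doubles; the pooled informative denominator also doubles
        assert two.informative == 2 * one.informative
        raw_one = one.arrays["chr1"] / one.scale
        raw_two = two.arrays["chr1"] / two.scale
        np.testing.assert_allclose(raw_two, 2 * raw_one)
        peak_one = one.arrays["chr1"][50_010]
        peak_two = two.arrays["chr1"][50_010]
        assert peak_two == pytest.approx(peak_one)  # 2x depth / 2x denominator

    def test_genic_reads_contribute_nothing(self, toy_transcripts):
        index = AnnotationIndex(toy_transcripts, {"chr1": 100_000})
        reads = self._reads([1_100, 2_500, 50_000])  # exonic, intronic, intergenic
        track = pool_intergenic_density({"a": (reads, 3)}, index, {"chr1": 100_000})
        arr = track.arrays["chr1"]
        assert arr[1_100] == 0 and arr[2_500] == 0 and arr[50_010] > 0

    def test_matches_brute_force_sum(self, toy_transcripts):
        index = AnnotationIndex(toy_transcripts, {"chr1": 100_000})
        rng = np.random.default_rng(9)
        samples = {}
        expected_reads = []
        for sid in ("s1", "s2", "s3"):
            starts = rng.integers(40_000, 90_000, size=20)
            reads = self._reads(starts.tolist())
            samples[sid] = (reads, 100)
            expected_reads += [("chr1", int(s), int(s) + 30) for s in starts]
        track = pool_intergenic_density(samples, index, {"chr1": 100_000})
        oracle = per_base_coverage(expected_reads, {"chr1": 100_000})
        scale = 1e7 / 300
        np.testing.assert_allclose(
            track.arrays["chr1"], np.array(oracle["chr1"], dtype=float) * scale
        )

    def test_no_intergenic_reads_fails(self, toy_transcripts):
        index = AnnotationIndex(toy_transcripts, {"chr1": 100_000})
        with pytest.raises(ValueError, match="no intergenic"):
            pool_intergenic_density(
                {"a": (self._reads([1_100]), 1)}, index, {"chr1": 100_000}
            )

    def test_empty_sample_map_fails(self, toy_transcripts):
        index = AnnotationIndex(toy_transcripts, {"chr1": 100_000})
        with pytest.raises(ValueError):
            pool_intergenic_density({}, index, {"chr1": 100_000})


class TestRecoverPlanted:
    def test_identical_sets_give_unit_jaccard(self):
        planted = [("chr1", 0, 60_000), ("chr1", 100_000, 180_000)]
        report = recover_planted(planted, planted)
        assert report.mean_jaccard == 1.0
        assert report.unmatched_called == []

    def test_disjoint_sets_all_unmatched(self):
        report = recover_planted([("chr1", 0, 60_000)], [("chr1", 100_000, 160_000)])
        assert report.pairs["called_id"].isna().all()
        assert report.mean_jaccard == 0.0
        assert report.unmatched_called == ["interval_1"]


class TestRecoveryStudies:
    def test_planted_domains_recovered(self, domain_recovery_replicates):
        """Planted >=50 kb domains at high contrast: mean Jaccard >= 0.95."""
        from vlincseq.studies import mean_recovery_jaccard

        for result in domain_recovery_replicates:
            assert len(result.dataset.vlincs) == 4
            # every planted domain is found by some called domain
            assert result.report.pairs["called_id"].notna().all()
        assert mean_recovery_jaccard(domain_recovery_replicates) >= 0.95

    def test_negative_control_calls_nothing(self, negative_control_domains):
        """No planted signal over a sparse background: ~0 domains."""
        assert len(negative_control_domains) <= 1
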