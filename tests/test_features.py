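"""Feature representations against per-base brute-force oracles."""

import numpy as np
import pytest

from compartmarks.features import (
    DEFAULT_STATE_MAP,
    FeatureDescriptor,
    MarkTracks,
    build_feature_matrix,
    fraction_covered,
    peak_signal_mean,
    peak_signal_sum,
    state_fractions,
    whole_signal_mean,
)
from compartmarks.genomic_io import (
    CoverageTrack,
    GenomicInterval,
    Peak,
    Segmentation,
    SegmentationSegment,
)
from compartmarks.labeling import LabeledRegion, RegionLabel

from conftest import random_peaks


# ---------------------------------------------------------------------------
# Independent per-base oracles
# ---------------------------------------------------------------------------


def per_base_fraction(region, peaks):
    covered = np.zeros(region.length, dtype=bool)
    for p in peaks:
        if p.interval.chrom != region.chrom:
            continue
        s = max(p.interval.start, region.start) - region.start
        e = min(p.interval.end, region.end) - region.start
        if e > s:
            covered[s:e] = True
    return covered.sum() / region.length


def per_base_mean(region, steps):
    values = np.zeros(region.length)
    for iv, v in steps:
        if iv.chrom != region.chrom:
            continue
        s = max(iv.start, region.start) - region.start
        e = min(iv.end, region.end) - region.start
        if e > s:
            values[s:e] = v
    return values.mean()


def per_base_state_fractions(region, segments, state_map):
    rank = {"active": 0, "repressed": 1, "heterochromatin": 2}
    arr = np.zeros(region.length, dtype=int)
    for seg in segments:
        iv = seg.interval
        if iv.chrom != region.chrom:
            continue
        s = max(iv.start, region.start) - region.start
        e = min(iv.end, region.end) - region.start
        if e > s:
            arr[s:e] = np.maximum(arr[s:e], rank[state_map[seg.state]])
    n = region.length
    return {name: (arr == code).sum() / n for name, code in rank.items()}


# ---------------------------------------------------------------------------


class TestFractionCovered:
    def test_merged_union_counts_overlap_once(self):
        region = GenomicInterval("chr1", 0, 100)
        peaks = [
            Peak(GenomicInterval("chr1", 10, 20), 1.0),
            Peak(GenomicInterval("chr1", 15, 30), 1.0),
        ]
        assert fraction_covered(region, peaks) == pytest.approx(0.20)

    def test_no_overlap_is_zero(self):
        region = GenomicInterval("chr1", 0, 100)
        assert fraction_covered(region, [Peak(GenomicInterval("chr1", 200, 300), 1)]) == 0.0

    def test_matches_per_base_oracle(self, rng):
        for _ in range(300):
            start = int(rng.integers(0, 5000))
            region = GenomicInterval("chr1", start, start + int(rng.integers(1, 5000)))
            peaks = random_peaks(rng, n=int(rng.integers(0, 30)))
            assert fraction_covered(region, peaks) == pytest.approx(
                per_base_fraction(region, peaks), abs=1e-12
            )

    def test_invariant_under_peak_split(self, rng):
        region = GenomicInterval("chr1", 0, 10_000)
        for _ in range(50):
            s = int(rng.integers(0, 9000))
            e = s + int(rng.integers(2, 1000))
            mid = int(rng.integers(s + 1, e))
            whole = [Peak(GenomicInterval("chr1", s, e), 1.0)]
            split = [
                Peak(GenomicInterval("chr1", s, mid), 1.0),
                Peak(GenomicInterval("chr1", mid, e), 1.0),
            ]
            assert fraction_covered(region, whole) == pytest.approx(
                fraction_covered(region, split), abs=1e-15
            )

    def test_coverage_monotone_in_region_growth(self, rng):
        peaks = random_peaks(rng, n=15)
        start = 4000
        prev = 0.0
        for end in range(4500, 10_001, 500):
            region = GenomicInterval("chr1", start, end)
            covered_bp = fraction_covered(region, peaks) * region.length
            assert covered_bp >= prev - 1e-9
            prev = covered_bp


class TestPeakSignalAggregates:
    def test_sum_and_mean_full_signal(self):
        region = GenomicInterval("chr1", 0, 100)
        peaks = [
            Peak(GenomicInterval("chr1", 90, 200), 3.0),  # partial overlap
            Peak(GenomicInterval("chr1", 10, 20), 5.0),
            Peak(GenomicInterval("chr1", 300, 400), 99.0),  # no overlap
        ]
        assert peak_signal_sum(region, peaks) == pytest.approx(8.0)
        assert peak_signal_mean(region, peaks) == pytest.approx(4.0)

    def test_empty_overlap_convention(self):
        region = GenomicInterval("chr1", 0, 10)
        assert peak_signal_sum(region, []) == 0.0
        assert peak_signal_mean(region, []) == 0.0

    def test_matches_filter_then_aggregate_oracle(self, rng):
        for _ in range(200):
            start = int(rng.integers(0, 5000))
            region = GenomicInterval("chr1", start, start + int(rng.integers(1, 5000)))
            peaks = random_peaks(rng, n=int(rng.integers(0, 25)))
            hits = [
                p.signal
                for p in peaks
                if p.interval.start < region.end and p.interval.end > region.start
            ]
            assert peak_signal_sum(region, peaks) == pytest.approx(sum(hits))
            expected_mean = sum(hits) / len(hits) if hits else 0.0
            assert peak_signal_mean(region, peaks) == pytest.approx(expected_mean)

    def test_prorated_variant_scales_by_overlap(self):
        region = GenomicInterval("chr1", 0, 100)
        peaks = [Peak(GenomicInterval("chr1", 50, 150), 4.0)]  # half inside
        assert peak_signal_sum(region, peaks, prorate=True) == pytest.approx(2.0)


class TestWholeSignalMean:
    def test_constant_coverage(self):
        track = CoverageTrack({"chr1": ([0], [1000], [2.0])})
        assert whole_signal_mean(GenomicInterval("chr1", 100, 900), track) == 2.0

    def test_half_covered(self):
        track = CoverageTrack({"chr1": ([0], [50], [4.0])})
        assert whole_signal_mean(GenomicInterval("chr1", 0, 100), track) == 2.0

    def test_matches_per_base_oracle(self, rng):
        for _ in range(300):
            # random non-overlapping step function
            cuts = np.sort(rng.choice(10_000, size=int(rng.integers(2, 20)), replace=False))
            steps = []
            for s, e in zip(cuts[:-1], cuts[1:]):
                if rng.random() < 0.6:
                    steps.append(
                        (GenomicInterval("chr1", int(s), int(e)), float(rng.uniform(0, 5)))
                    )
            track = CoverageTrack.from_step_list(steps)
            start = int(rng.integers(0, 9000))
            region = GenomicInterval("chr1", start, start + int(rng.integers(1, 1000)))
            assert whole_signal_mean(region, track) == pytest.approx(
                per_base_mean(region, steps), abs=1e-12
            )

    def test_region_inside_one_step_is_exact(self):
        track = CoverageTrack({"chr1": ([100], [10_000], [3.7])})
        assert whole_signal_mean(GenomicInterval("chr1", 500, 700), track) == 3.7


class TestStateFractions:
    def test_fully_heterochromatin(self):
        seg = Segmentation(
            [SegmentationSegment(GenomicInterval("chr1", 0, 100), "heterochromatin")]
        )
        fr = state_fractions(GenomicInterval("chr1", 0, 100), seg)
        assert fr == {"active": 0.0, "repressed": 0.0, "heterochromatin": 1.0}

    def test_unsegmented_defaults_to_active(self):
        fr = state_fractions(GenomicInterval("chr1", 0, 100), Segmentation([]))
        assert fr == {"active": 1.0, "repressed": 0.0, "heterochromatin": 0.0}

    def test_unmapped_state_is_config_error(self):
        seg = Segmentation(
            [SegmentationSegment(GenomicInterval("chr1", 0, 100), "quiescent")]
        )
        with pytest.raises(ValueError, match="quiescent"):
            state_fractions(GenomicInterval("chr1", 0, 100), seg)

    def test_matches_per_base_oracle_and_sums_to_one(self, rng):
        states = list(DEFAULT_STATE_MAP)
        for _ in range(200):
            segments = []
            for _ in range(int(rng.integers(0, 15))):
                s = int(rng.integers(0, 9000))
                segments.append(
                    SegmentationSegment(
                        GenomicInterval("chr1", s, s + int(rng.integers(1, 2000))),
                        states[int(rng.integers(len(states)))],
                    )
                )
            seg = Segmentation(segments)
            start = int(rng.integers(0, 8000))
            region = GenomicInterval("chr1", start, start + int(rng.integers(1, 2000)))
            got = state_fractions(region, seg)
            want = per_base_state_fractions(region, segments, DEFAULT_STATE_MAP)
            assert sum(got.values()) == pytest.approx(1.0, abs=1e-12)
            for k in want:
                assert got[k] == pytest.approx(want[k], abs=1e-12)


class TestBuildFeatureMatrix:
    def _regions(self, n=3):
        return [
            LabeledRegion(
                f"r{i}",
                GenomicInterval("chr1", i * 1000, (i + 1) * 1000),
                RegionLabel.A if i % 2 == 0 else RegionLabel.B,
                "window",
            )
            for i in range(n)
        ]

    def _catalog(self, rng):
        return {
            "m1": MarkTracks(peaks=random_peaks(rng, n=10, span=3000)),
            "m2": MarkTracks(coverage=CoverageTrack({"chr1": ([0], [3000], [1.5])})),
        }

    def test_shape_and_column_order(self, rng):
        plan = [
            FeatureDescriptor("m1", "fraction"),
            FeatureDescriptor("m1", "peak_sum"),
            FeatureDescriptor("m2", "whole_signal_mean"),
        ]
        matrix = build_feature_matrix(self._regions(), self._catalog(rng), plan)
        assert matrix.values.shape == (3, 3)
        assert matrix.feature_ids == [
            "m1:fraction", "m1:peak_sum", "m2:whole_signal_mean",
        ]
        assert np.all(matrix.values[:, 2] == 1.5)

    def test_missing_track_fails_before_compute(self, rng):
        plan = [FeatureDescriptor("m1", "whole_signal_mean")]  # m1 has no coverage
        with pytest.raises(KeyError, match="coverage"):
            build_feature_matrix(self._regions(), self._catalog(rng), plan)
        with pytest.raises(KeyError, match="catalog"):
            build_feature_matrix(
                self._regions(), self._catalog(rng), [FeatureDescriptor("nope", "fraction")]
            )

    def test_region_permutation_permutes_rows(self, rng):
        plan = [
            FeatureDescriptor("m1", "fraction"),
            FeatureDescriptor("m2", "whole_signal_mean"),
        ]
        regions = self._regions(5)
        catalog = self._catalog(rng)
        base = build_feature_matrix(regions, catalog, plan)
        perm = [3, 0, 4, 1, 2]
        shuffled = build_feature_matrix([regions[i] for i in perm], catalog, plan)
        assert np.array_equal(shuffled.values, base.values[perm])
        assert shuffled.region_ids == [base.region_ids[i] for i in perm]

    def test_recomputation_is_bit_identical(self, rng):
        plan = [FeatureDescriptor("m1", "peak_mean")]
        regions = self._regions()
        catalog = self._catalog(rng)
        a = build_feature_matrix(regions, catalog, plan)
        b = build_feature_matrix(regions, catalog, plan)
        assert np.array_equal(a.values, b.values)
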