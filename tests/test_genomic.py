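"""Interval containers, interval arithmetic and metaprofiles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from repliq.genomic import (
    CoverageTrack,
    GenomeLayout,
    GenomicInterval,
    IntervalSet,
    bin_genome,
    central_window,
    count_overlaps,
    filter_min_length,
    merge_within,
    metaprofile,
    overlap_fraction,
)


def brute_force_overlaps(query, features):
    return np.array([
        sum(1 for f in features if q.overlaps(f)) for q in query
    ])


def random_interval_set(rng, n, chrom_len=100_000, chroms=("chr1", "chr2")):
    ivs = []
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, chrom_len - 1))
        end = int(rng.integers(start + 1, min(chrom_len, start + 5_000) + 1))
        ivs.append(GenomicInterval(chrom, start, end))
    return IntervalSet(ivs)


class TestTypes:
    def test_interval_invariants(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 100, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 100, 50)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -5, 50)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 0, 50, strand="x")

    def test_layout_invariants(self):
        with pytest.raises(ValueError):
            GenomeLayout({"chr1": 0})
        with pytest.raises(ValueError):
            GenomeLayout([("chr1", 10), ("chr1", 20)])

    def test_interval_set_sorted_and_validated(self, layout):
        s = IntervalSet(
            [GenomicInterval("chr2", 5, 10), GenomicInterval("chr1", 0, 3)],
            layout=layout,
        )
        assert [iv.chrom for iv in s] == ["chr1", "chr2"]
        with pytest.raises(ValueError):
            IntervalSet([GenomicInterval("chr2", 0, 600_000)], layout=layout)

    def test_track_shape_and_sign_checks(self, layout):
        with pytest.raises(ValueError):
            CoverageTrack(layout, 1000, {"chr1": np.zeros(5), "chr2": np.zeros(500)})
        with pytest.raises(ValueError):
            CoverageTrack(
                layout, 1000,
                {"chr1": -np.ones(1000), "chr2": np.zeros(500)}, units="RPM",
            )
        # signed units allow negatives
        CoverageTrack(
            layout, 1000,
            {"chr1": -np.ones(1000), "chr2": np.zeros(500)}, units="log-ratio",
        )


class TestBinGenome:
    @pytest.mark.parametrize(
        "length,bin_size,expected",
        [
            (120_000, 50_000, [(0, 50_000), (50_000, 100_000), (100_000, 120_000)]),
            (100_000, 10_000, [(i * 10_000, (i + 1) * 10_000) for i in range(10)]),
            (30_000, 50_000, [(0, 30_000)]),
        ],
    )
    def test_examples(self, length, bin_size, expected):
        bins = bin_genome(GenomeLayout({"c": length}), bin_size)
        assert [(iv.start, iv.end) for iv in bins] == expected

    def test_tiling_no_gaps(self, layout):
        bins = bin_genome(layout, 7_000)
        for chrom in layout:
            ivs = [iv for iv in bins if iv.chrom == chrom]
            assert ivs[0].start == 0 and ivs[-1].end == layout[chrom]
            assert all(a.end == b.start for a, b in zip(ivs, ivs[1:]))
            assert sum(len(iv) for iv in ivs) == layout[chrom]


class TestMergeWithin:
    def test_examples(self):
        s = IntervalSet([GenomicInterval("c", 0, 8000), GenomicInterval("c", 12000, 20000)])
        assert [(iv.start, iv.end) for iv in merge_within(s, 10_000)] == [(0, 20000)]
        s2 = IntervalSet([GenomicInterval("c", 0, 8000), GenomicInterval("c", 30000, 60000)])
        assert len(merge_within(s2, 10_000)) == 2
        single = IntervalSet([GenomicInterval("c", 5, 10)])
        assert merge_within(single, 10_000) == single

    @given(st.integers(0, 10_000), st.data())
    @settings(max_examples=50, deadline=None)
    def test_idempotent_and_separated(self, gap, data):
        n = data.draw(st.integers(1, 30))
        seed = data.draw(st.integers(0, 2**31 - 1))
        rng = np.random.default_rng(seed)
        s = random_interval_set(rng, n)
        once = merge_within(s, gap)
        assert merge_within(once, gap) == once
        by_chrom = once.by_chrom()
        for ivs in by_chrom.values():
            for a, b in zip(ivs, ivs[1:]):
                assert b.start - a.end > gap
        # union of covered positions is preserved
        assert sum(count_overlaps(s, once) >= 1) == len(s)
        assert once.total_length() >= max(len(iv) for iv in s)


class TestFilterAndWindow:
    def test_filter_min_length_boundary_inclusive(self):
        s = IntervalSet([GenomicInterval("c", 0, 20_000), GenomicInterval("c", 30_000, 49_999)])
        kept = filter_min_length(s, 20_000)
        assert [(iv.start, iv.end) for iv in kept] == [(0, 20_000)]
        assert len(filter_min_length(IntervalSet(), 5)) == 0

    def test_central_window(self):
        layout = GenomeLayout({"c": 300_000})
        iv = central_window(GenomicInterval("c", 0, 250_000), 50_000, layout)
        assert (iv.start, iv.end) == (100_000, 150_000)
        short = GenomicInterval("c", 0, 40_000)
        assert central_window(short, 50_000, layout) == short
        near_end = central_window(GenomicInterval("c", 200_000, 300_000), 80_000, layout)
        assert (near_end.start, near_end.end) == (210_000, 290_000)
        assert near_end.end <= layout["c"]


class TestCountOverlaps:
    def test_half_open_convention(self):
        q = IntervalSet([GenomicInterval("c", 0, 100)])
        f = IntervalSet([GenomicInterval("c", 50, 150), GenomicInterval("c", 200, 300)])
        assert count_overlaps(q, f).tolist() == [1]
        abutting = IntervalSet([GenomicInterval("c", 100, 150)])
        assert count_overlaps(q, abutting).tolist() == [0]
        assert count_overlaps(q, IntervalSet()).tolist() == [0]

    def test_matches_brute_force(self, rng):
        for _ in range(50):
            q = random_interval_set(rng, int(rng.integers(1, 50)))
            f = random_interval_set(rng, int(rng.integers(0, 50)))
            assert count_overlaps(q, f).tolist() == brute_force_overlaps(q, f).tolist()

    def test_overlap_fraction(self):
        q = IntervalSet([GenomicInterval("c", 0, 100)])
        f = IntervalSet([GenomicInterval("c", 25, 50), GenomicInterval("c", 40, 75)])
        assert overlap_fraction(q, f)[0] == pytest.approx(0.5)


class TestMetaprofile:
    def _track(self, values, bin_size=10):
        layout = GenomeLayout({"c": len(values) * bin_size})
        return CoverageTrack(layout, bin_size, {"c": np.asarray(values, float)})

    def test_constant_track_flat_profile(self):
        track = self._track([2.0] * 100)
        anchors = IntervalSet([GenomicInterval("c", 400, 401), GenomicInterval("c", 600, 601)])
        _, mean, _ = metaprofile(track, anchors, 100, 100)
        assert np.allclose(mean, 2.0)

    def test_single_anchor_identity(self):
        track = self._track(np.arange(100.0))
        anchors = IntervalSet([GenomicInterval("c", 500, 501)])
        rows, mean, _ = metaprofile(track, anchors, 50, 50)
        assert np.allclose(rows[0], mean)

    def test_planted_symmetric_peak(self, rng):
        vals = np.ones(200)
        centers = [500, 1210, 1750]
        layout = GenomeLayout({"c": 2000})
        track_vals = np.ones(200)
        for c in centers:
            b = c // 10
            track_vals[b - 3 : b + 4] += [1, 2, 5, 9, 5, 2, 1]
        track = CoverageTrack(layout, 10, {"c": track_vals})
        anchors = IntervalSet([GenomicInterval("c", c, c + 1) for c in centers])
        _, mean, _ = metaprofile(track, anchors, 100, 100)
        peak = int(np.argmax(mean))
        assert peak == len(mean) // 2
        for k in range(1, 7):   # symmetric about the peak column
            assert mean[peak - k] == pytest.approx(mean[peak + k])

    def test_off_chromosome_positions_excluded(self):
        track = self._track(np.full(100, 3.0))
        anchors = IntervalSet([GenomicInterval("c", 5, 6)])
        rows, mean, _ = metaprofile(track, anchors, 200, 200)
        assert np.isnan(rows[0][0])
        assert np.nanmax(mean) == 3.0
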