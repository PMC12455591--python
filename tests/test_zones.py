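"""Initiation-zone calling, differential classification, enrichment."""

import itertools

import numpy as np
import pandas as pd
import pytest

from repliq.genomic import CoverageTrack, GenomeLayout, GenomicInterval, IntervalSet
from repliq.zones import (
    call_zones,
    classify_zones,
    count_reads_in_intervals,
    fork_progression,
    hyperactivation_test,
    permutation_enrichment,
    threshold_call_peaks,
    zone_gene_abundance,
    zone_statistics,
    zone_summits,
)


def flat_track(n_bins, value=5.0, bin_size=1000, rng=None):
    layout = GenomeLayout({"c": n_bins * bin_size})
    vals = np.full(n_bins, float(value)) if rng is None else rng.poisson(value, n_bins).astype(float)
    return CoverageTrack(layout, bin_size, {"c": vals})


class TestPeakCalling:
    def test_flat_background_empty(self, rng):
        assert len(threshold_call_peaks(flat_track(2000, 5.0, rng=rng))) == 0
        assert len(threshold_call_peaks(flat_track(100, 0.0))) == 0

    def test_single_plateau_recovered(self, rng):
        track = flat_track(2000, 5.0, rng=rng)
        track.data["c"][500:600] = rng.poisson(50.0, 100)
        peaks = threshold_call_peaks(track)
        assert len(peaks) == 1
        iv = peaks[0]
        covered = max(0, min(iv.end, 600_000) - max(iv.start, 500_000))
        assert covered / 100_000 >= 0.9

    def test_two_plateaus_two_peaks(self, rng):
        track = flat_track(2000, 5.0, rng=rng)
        track.data["c"][500:600] = rng.poisson(50.0, 100)
        track.data["c"][650:750] = rng.poisson(50.0, 100)
        assert len(threshold_call_peaks(track)) == 2


class TestCallZones:
    def test_merge_and_filter_composition(self):
        peaks = IntervalSet([GenomicInterval("c", 0, 8000), GenomicInterval("c", 12000, 20000)])
        zones = call_zones([peaks])
        assert [(z.start, z.end) for z in zones] == [(0, 20000)]

    def test_short_region_dropped(self):
        assert len(call_zones([IntervalSet([GenomicInterval("c", 0, 15000)])])) == 0

    def test_any_sample_union_semantics(self):
        s1 = IntervalSet([GenomicInterval("c", 0, 25_000)])
        s2 = IntervalSet([GenomicInterval("c", 100_000, 130_000)])
        zones = call_zones([s1, s2])
        assert [(z.start, z.end) for z in zones] == [(0, 25_000), (100_000, 130_000)]


class TestZoneStatistics:
    def _counts(self, rows):
        df = pd.DataFrame(rows, columns=["control_rep1", "control_rep2",
                                         "ko_rep1", "ko_rep2"])
        df.insert(0, "chrom", "c")
        df.insert(1, "start", np.arange(len(df)) * 100_000)
        df.insert(2, "end", np.arange(len(df)) * 100_000 + 50_000)
        df.insert(3, "name", [f"z{i}" for i in range(len(df))])
        return df

    DESIGN = {"control_rep1": "control", "control_rep2": "control",
              "ko_rep1": "ko", "ko_rep2": "ko"}
    LIBS = {s: 1e6 for s in DESIGN}

    def test_null_zone(self):
        counts = self._counts([[500, 500, 500, 500]])
        zones = IntervalSet([GenomicInterval("c", 0, 50_000)])
        out = zone_statistics(zones, counts, self.DESIGN, lib_sizes=self.LIBS)
        assert out.loc[0, "lfc"] == pytest.approx(0.0)
        assert out.loc[0, "pvalue"] > 0.9

    def test_twofold_concentrations(self):
        counts = self._counts([[128, 128, 256, 256]])
        zones = IntervalSet([GenomicInterval("c", 0, 50_000)])
        out = zone_statistics(zones, counts, self.DESIGN, lib_sizes=self.LIBS)
        assert out.loc[0, "conc_ko"] == pytest.approx(np.log2(257), abs=1e-6)
        assert out.loc[0, "conc_control"] == pytest.approx(np.log2(129), abs=1e-6)
        assert out.loc[0, "lfc"] == pytest.approx(np.log2(257) - np.log2(129), abs=1e-6)

    def test_zero_count_zone_missing(self):
        counts = self._counts([[0, 0, 0, 0], [10, 10, 10, 10]])
        zones = IntervalSet([GenomicInterval("c", 0, 50_000),
                             GenomicInterval("c", 100_000, 150_000)])
        out = zone_statistics(zones, counts, self.DESIGN, lib_sizes=self.LIBS)
        assert np.isnan(out.loc[0, "pvalue"]) and np.isnan(out.loc[0, "lfc"])
        assert np.isfinite(out.loc[1, "pvalue"])

    def test_library_size_normalization(self):
        # same rates, one library twice as deep: no fold change
        counts = self._counts([[100, 100, 200, 200]])
        libs = {"control_rep1": 1e6, "control_rep2": 1e6,
                "ko_rep1": 2e6, "ko_rep2": 2e6}
        zones = IntervalSet([GenomicInterval("c", 0, 50_000)])
        out = zone_statistics(zones, counts, self.DESIGN, lib_sizes=libs)
        assert out.loc[0, "lfc"] == pytest.approx(0.0, abs=1e-6)
        assert out.loc[0, "pvalue"] > 0.9


class TestClassification:
    def _stats(self, rows):
        df = pd.DataFrame(rows, columns=["conc_control", "conc_ko", "lfc", "fdr"])
        df.insert(0, "name", [f"z{i}" for i in range(len(df))])
        return df

    @pytest.mark.parametrize(
        "row,expected",
        [
            ((6.0, 8.0, 0.9, 1e-12), "activated"),
            ((8.0, 8.0, 0.5, 1e-12), "constitutive"),
            ((5.0, 6.0, -0.9, 1e-12), "constitutive"),   # fails conc gate
            ((8.0, 6.0, -0.9, 1e-12), "deactivated"),
            ((8.0, 8.0, 0.9, 1e-5), "constitutive"),     # fails FDR gate
        ],
    )
    def test_threshold_gates(self, row, expected):
        out = classify_zones(self._stats([row]))
        assert out.loc[0, "class"] == expected

    def test_order_invariance(self, rng):
        rows = [
            (rng.uniform(5, 9), rng.uniform(5, 9), rng.uniform(-2, 2),
             10.0 ** rng.uniform(-15, 0))
            for _ in range(30)
        ]
        df = self._stats(rows)
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        out1 = classify_zones(df).set_index("name")["class"]
        out2 = classify_zones(shuffled).set_index("name")["class"]
        assert out1.sort_index().equals(out2.sort_index())


class TestHyperactivation:
    def test_paired_shift_detected(self, rng):
        ctrl = rng.lognormal(8, 0.5, 20)
        ko = ctrl * 1.3 * rng.lognormal(0, 0.02, 20)
        _, p = hyperactivation_test(ctrl, ko)
        assert p < 0.01
        _, p_null = hyperactivation_test(ctrl, ctrl * rng.lognormal(0, 0.02, 20))
        assert p_null > 0.01


class TestPermutationEnrichment:
    def test_exact_toy_enumeration(self):
        # background of 4 windows, features hitting exactly 2 of them;
        # query = the two feature-bearing windows
        background = IntervalSet([
            GenomicInterval("c", i * 10_000, i * 10_000 + 5_000) for i in range(4)
        ])
        features = IntervalSet([
            GenomicInterval("c", 1_000, 2_000), GenomicInterval("c", 11_000, 12_000),
        ])
        query = IntervalSet(list(background)[:2])
        # exact null: all C(4,2)=6 equally likely subsets; only one reaches 2
        per = [1, 1, 0, 0]
        exact = np.mean([
            sum(np.array(per)[list(c)]) >= 2
            for c in itertools.combinations(range(4), 2)
        ])
        res = permutation_enrichment(query, features, background, n=5000, seed=11)
        assert res.observed == 2
        assert res.p_value == pytest.approx(exact, abs=0.02)

    def test_query_equals_background(self):
        background = IntervalSet([
            GenomicInterval("c", i * 10_000, i * 10_000 + 5_000) for i in range(4)
        ])
        features = IntervalSet([GenomicInterval("c", 1_000, 2_000)])
        res = permutation_enrichment(background, features, background, n=100, seed=0)
        assert res.p_value == pytest.approx(1.0)
        assert np.isnan(res.z)

    def test_minimum_attainable_p(self, rng):
        background = IntervalSet([
            GenomicInterval("c", i * 10_000, i * 10_000 + 5_000) for i in range(50)
        ])
        features = IntervalSet([GenomicInterval("c", 1_000, 2_000)])
        query = IntervalSet([background[0]])
        res = permutation_enrichment(query, features, background, n=200, seed=5)
        assert res.p_value >= 1 / 201

    def test_genome_mode_needs_layout(self):
        q = IntervalSet([GenomicInterval("c", 0, 100)])
        with pytest.raises(ValueError, match="layout"):
            permutation_enrichment(q, q, mode="genome")


class TestZoneContext:
    def test_gene_abundance(self):
        layout = GenomeLayout({"c": 1_000_000})
        zones = IntervalSet([GenomicInterval("c", 0, 200_000),
                             GenomicInterval("c", 400_000, 600_000)])
        assert zone_gene_abundance({"k": zones}, IntervalSet(), layout)["k"] == 0.0
        genes = IntervalSet([GenomicInterval("c", 99_000, 101_000),
                             GenomicInterval("c", 499_000, 501_000)])
        assert zone_gene_abundance({"k": zones}, genes, layout)["k"] == 1.0

    def test_fork_progression_profiles(self, rng):
        layout = GenomeLayout({"c": 2_000_000})
        vals = rng.poisson(5.0, 2000).astype(float)
        vals[950:1050] += 40.0
        track = CoverageTrack(layout, 1000, {"c": vals})
        zones = IntervalSet([GenomicInterval("c", 900_000, 1_100_000)])
        summits = zone_summits(track, zones)
        assert abs(summits[0].start - 1_000_000) < 60_000
        out = fork_progression({"a": track, "b": track}, summits, window=200_000)
        assert np.allclose(out["a"][0], out["b"][0], equal_nan=True)

    def test_wider_plateau_wider_shoulders(self):
        layout = GenomeLayout({"c": 2_000_000})
        narrow = np.ones(2000); narrow[990:1010] = 50.0
        wide = np.ones(2000); wide[950:1050] = 50.0
        t_narrow = CoverageTrack(layout, 1000, {"c": narrow})
        t_wide = CoverageTrack(layout, 1000, {"c": wide})
        summits = IntervalSet([GenomicInterval("c", 1_000_000, 1_000_001)])
        out = fork_progression({"n": t_narrow, "w": t_wide}, summits, 200_000)
        frac_high_n = np.mean(out["n"][0] > 25)
        frac_high_w = np.mean(out["w"][0] > 25)
        assert frac_high_w > frac_high_n
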