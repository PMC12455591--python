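"""ChIP scaling, knockout-background correction and signal associations."""

import numpy as np
import pytest

from repliq.chip import (
    common_peak_scale,
    compartment_signal,
    gene_quartile_signal,
    genome_fraction_marked,
    knockout_correct,
    log2_ratio,
    profile_similarity,
    spikein_scale,
    subtract_background,
)
from repliq.genomic import CoverageTrack, GenomeLayout, GenomicInterval, IntervalSet


def make_track(values, bin_size=1000, units="raw"):
    layout = GenomeLayout({"c": len(values) * bin_size})
    return CoverageTrack(layout, bin_size, {"c": np.asarray(values, float)}, units=units)


class TestScaling:
    def test_spikein_rpm(self):
        f = spikein_scale({"a": 1_000_000, "b": 2_000_000})
        assert f["a"] == pytest.approx(1.0)
        assert f["b"] == pytest.approx(0.5)
        with pytest.raises(ValueError):
            spikein_scale({"a": 0})

    def test_common_peak_factors(self, rng):
        counts = {"a": np.full(100, 2e4), "b": np.full(100, 1e4)}
        f = common_peak_scale(counts, top_n=100)
        assert f["a"] == pytest.approx(0.75)
        assert f["b"] == pytest.approx(1.5)
        equal = common_peak_scale({"a": np.ones(10), "b": np.ones(10)})
        assert equal["a"] == equal["b"] == pytest.approx(1.0)
        # postcondition: scaled totals agree
        scaled = [counts[s].sum() * f[s] for s in counts]
        assert abs(scaled[0] - scaled[1]) < 1e-9
        with pytest.raises(ValueError, match="zero reads"):
            common_peak_scale({"a": np.ones(5), "b": np.zeros(5)})

    def test_uniform_rescaling_equivariance(self, rng):
        counts = {"a": rng.poisson(100, 50).astype(float) + 1,
                  "b": rng.poisson(150, 50).astype(float) + 1}
        f1 = common_peak_scale(counts)
        # factors are invariant under a uniform rescaling of all inputs, so
        # the corrected signal scales exactly with the data
        f2 = common_peak_scale({k: 3.0 * v for k, v in counts.items()})
        for s in counts:
            assert f2[s] == pytest.approx(f1[s])
        # deepening one library divides its factor accordingly
        f3 = common_peak_scale({"a": counts["a"], "b": 2.0 * counts["b"]})
        assert f3["b"] * 2.0 * counts["b"].sum() == pytest.approx(
            f3["a"] * counts["a"].sum()
        )


class TestSubtraction:
    def test_examples(self):
        ctrl = make_track([5.0, 1.0, 4.0])
        ko = make_track([2.0, 2.0, 0.0])
        corr = subtract_background(ctrl, ko)
        assert corr.track.data["c"].tolist() == [3.0, 0.0, 4.0]
        assert corr.track.units == "corrected"
        raw = subtract_background(ctrl, ko, clip_negative=False)
        assert raw.track.data["c"].tolist() == [3.0, -1.0, 4.0]
        assert raw.track.units == "difference"

    def test_zero_ko_is_identity(self):
        ctrl = make_track([5.0, 1.0, 4.0])
        zero = make_track([0.0, 0.0, 0.0])
        corr = subtract_background(ctrl, zero)
        assert np.allclose(corr.track.data["c"], ctrl.data["c"])

    def test_grid_mismatch(self):
        with pytest.raises(ValueError, match="grid"):
            subtract_background(make_track([1.0, 2.0]), make_track([1.0], bin_size=2000))

    def test_log2_ratio(self):
        a = make_track([4.0, 8.0])
        b = make_track([4.0, 2.0])
        lr = log2_ratio(a, b, pseudocount=1e-9)
        assert lr.data["c"][0] == pytest.approx(0.0, abs=1e-6)
        assert lr.data["c"][1] == pytest.approx(2.0, abs=1e-6)
        anti = log2_ratio(b, a, pseudocount=1e-9)
        assert np.allclose(lr.data["c"], -anti.data["c"])


class TestGenomeFraction:
    def test_recovers_mixture_weight(self, rng):
        # 60% low-mode bins, 40% well-separated high-mode bins
        n = 5000
        low = rng.gamma(2.0, 0.5, int(n * 0.6))
        high = rng.gamma(40.0, 1.5, n - int(n * 0.6))
        vals = np.concatenate([low, high])
        rng.shuffle(vals)
        track = make_track(vals, bin_size=10_000)
        res = genome_fraction_marked(track, bin_size=10_000)
        assert abs(res.fraction_marked - 40.0) <= 5.0
        # threshold lies between the two mode locations (log1p scale)
        assert np.log1p(1.0) < res.threshold < np.log1p(60.0)

    def test_unimodal_is_an_error(self, rng):
        vals = rng.gamma(5.0, 1.0, 5000)
        with pytest.raises(ValueError, match="bimodal"):
            genome_fraction_marked(make_track(vals, 10_000), 10_000)


class TestCompartments:
    def _setup(self, rng, a_mult=2.0, n_bins=60):
        half = n_bins * 50_000
        layout = GenomeLayout({"c": 2 * half})
        a = IntervalSet([GenomicInterval("c", 0, half)])
        b = IntervalSet([GenomicInterval("c", half, 2 * half)])
        vals = np.concatenate([
            rng.gamma(4.0, a_mult, n_bins), rng.gamma(4.0, 1.0, n_bins)
        ])
        return CoverageTrack(layout, 50_000, {"c": vals}), a, b

    def test_planted_difference_detected(self, rng):
        track, a, b = self._setup(rng, a_mult=2.0)
        av, bv, p = compartment_signal(track, a, b)
        assert np.median(av) / np.median(bv) == pytest.approx(2.0, rel=0.5)
        assert p < 0.01

    def test_null(self):
        layout = GenomeLayout({"c": 2_000_000})
        a = IntervalSet([GenomicInterval("c", 0, 1_000_000)])
        b = IntervalSet([GenomicInterval("c", 1_000_000, 2_000_000)])
        track = CoverageTrack(layout, 50_000, {"c": np.full(40, 3.0)})
        av, bv, p = compartment_signal(track, a, b)
        assert np.median(av) == np.median(bv)
        assert p > 0.05

    def test_majority_rule_and_overlap_error(self, rng):
        layout = GenomeLayout({"c": 100_000})
        a = IntervalSet([GenomicInterval("c", 0, 30_000)])       # 60% of bin 1
        b = IntervalSet([GenomicInterval("c", 30_000, 50_000)])  # 40% of bin 1
        track = CoverageTrack(layout, 50_000, {"c": np.array([7.0, 1.0])})
        av, bv, _ = compartment_signal(track, a, b)
        assert 7.0 in av and 7.0 not in bv
        with pytest.raises(ValueError, match="overlap"):
            bad_b = IntervalSet([GenomicInterval("c", 20_000, 50_000)])
            compartment_signal(track, a, bad_b)


class TestGeneQuartiles:
    def _genes(self, n=40, length=10_000):
        return IntervalSet([
            GenomicInterval("c", i * 20_000, i * 20_000 + length, f"g{i}")
            for i in range(n)
        ])

    def test_top_quartile_median_is_one(self, rng):
        genes = self._genes()
        layout = GenomeLayout({"c": 1_000_000})
        track = CoverageTrack(layout, 1000, {"c": rng.gamma(5, 1, 1000)})
        expr = rng.lognormal(0, 1, len(genes))
        groups, _ = gene_quartile_signal(track, genes, expr)
        assert np.median(groups[3]) == pytest.approx(1.0)

    def test_monotone_signal_expression_relation(self, rng):
        genes = self._genes()
        expr = np.arange(len(genes), dtype=float) + 1
        vals = np.ones(1000)
        for i in range(len(genes)):
            vals[i * 20 : i * 20 + 10] = expr[i]
        layout = GenomeLayout({"c": 1_000_000})
        track = CoverageTrack(layout, 1000, {"c": vals})
        groups, p = gene_quartile_signal(track, genes, expr)
        medians = [np.median(g) for g in groups]
        assert medians == sorted(medians)
        assert p < 0.01

    def test_missing_expression_reported(self, rng):
        genes = self._genes(10)
        layout = GenomeLayout({"c": 1_000_000})
        track = CoverageTrack(layout, 1000, {"c": np.ones(1000)})
        expr = np.ones(10)
        expr[3] = np.nan
        with pytest.raises(ValueError, match="g3"):
            gene_quartile_signal(track, genes, expr)


class TestProfileSimilarity:
    def test_rank_properties(self):
        base = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        mono = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        labels, rho, link = profile_similarity({
            "x": base, "same": base.copy(), "scaled": 3 * base,
            "mono": mono, "mono_rev": mono[::-1].copy(),
        })
        i = {l: k for k, l in enumerate(labels)}
        assert rho[i["x"], i["same"]] == pytest.approx(1.0)
        assert rho[i["x"], i["scaled"]] == pytest.approx(1.0)
        # a strictly reversed monotone profile is perfectly anticorrelated
        assert rho[i["mono"], i["mono_rev"]] == pytest.approx(-1.0)
        assert link is not None

    def test_constant_profile_missing(self):
        labels, rho, _ = profile_similarity({
            "x": np.array([1.0, 2.0, 3.0]), "flat": np.ones(3),
        })
        assert np.isnan(rho[0, 1])


class TestKnockoutCorrect:
    def test_recovery_on_small_study(self, small_study):
        corr = knockout_correct(small_study.chip.control, small_study.chip.ko)
        truth = small_study.truth.specific_chip.values()
        r = np.corrcoef(corr.track.values(), truth)[0, 1]
        assert r >= 0.9

    def test_corrected_signal_enriched_in_a_compartments(self, small_study):
        """The planted mark is biased to euchromatic (A) domains, and the
        corrected track shows it: higher signal in A than B."""
        corr = knockout_correct(small_study.chip.control, small_study.chip.ko)
        tr = small_study.truth
        av, bv, p = compartment_signal(
            corr.track, tr.compartments_a, tr.compartments_b
        )
        assert np.median(av) > np.median(bv)
        assert p < 0.01

    def test_spikein_route_matches_common_peak_route(self, small_study):
        c1 = knockout_correct(small_study.chip.control, small_study.chip.ko)
        c2 = knockout_correct(
            small_study.chip.control, small_study.chip.ko,
            scaling="spike-in", spikein_reads=small_study.chip.spikein,
        )
        # same biology up to a global scale: near-perfect correlation
        r = np.corrcoef(c1.track.values(), c2.track.values())[0, 1]
        assert r >= 0.99
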