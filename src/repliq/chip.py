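"""Knockout-corrected quantitative ChIP signal.

The KO sample carries only antibody background (nonspecific peaks), so after
putting control and KO libraries on a common scale — by spike-in RPM or by
equalizing read totals over shared peaks — the KO track can be subtracted
from the control track to leave specific signal, with negatives clipped to
zero. Downstream summaries: fraction of the genome marked (bimodal 10 kb-bin
histogram), signal split by A/B compartment, signal across gene-expression
quartiles, and shape similarity between averaged profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .genomic import CoverageTrack, GenomicInterval, IntervalSet, overlap_fraction

__all__ = [
    "ScalingFactors",
    "CorrectedTrack",
    "PositivityResult",
    "spikein_scale",
    "common_peak_scale",
    "knockout_correct",
    "subtract_background",
    "log2_ratio",
    "genome_fraction_marked",
    "compartment_signal",
    "gene_quartile_signal",
    "profile_similarity",
]


@dataclass(frozen=True)
class ScalingFactors:
    """Per-sample multiplicative scaling factors."""

    factors: Dict[str, float]
    method: str          # "spike-in RPM" | "common-peak"

    def __post_init__(self):
        for name, f in self.factors.items():
            if not (f > 0 and np.isfinite(f)):
                raise ValueError(f"scaling factor for {name!r} must be positive")

    def __getitem__(self, sample: str) -> float:
        return self.factors[sample]


@dataclass
class CorrectedTrack:
    """A background-corrected coverage track with provenance."""

    track: CoverageTrack
    control_id: str
    ko_id: str
    scaling_method: str


@dataclass
class PositivityResult:
    """Genome-fraction-marked summary from the bimodal bin histogram.

    ``threshold`` is on the log1p(signal) scale used for the histogram.
    """

    threshold: float
    fraction_marked: float        # percent of bins above threshold
    bin_edges: np.ndarray
    frequencies: np.ndarray
    n_bins: int


def spikein_scale(spikein_reads: Mapping[str, int]) -> ScalingFactors:
    """Reads-per-million scaling on exogenous spike-in reads:
    ``factor = 1e6 / spikein_reads``."""
    factors = {}
    for sample, reads in spikein_reads.items():
        if reads <= 0:
            raise ValueError(f"sample {sample!r} has no spike-in reads")
        factors[sample] = 1e6 / reads
    return ScalingFactors(factors, method="spike-in RPM")


def common_peak_scale(
    peak_counts: Mapping[str, np.ndarray], top_n: int = 10_000
) -> ScalingFactors:
    """Scale samples so read totals over the top shared peaks are equal.

    ``peak_counts`` maps sample -> per-peak read counts over one common peak
    list. Peaks are ranked by combined count across samples; the ``top_n``
    highest enter each sample's total ``T_i`` and ``factor_i = mean_j(T_j) /
    T_i``, so scaled totals agree exactly.
    """
    names = list(peak_counts)
    mat = np.vstack([np.asarray(peak_counts[s], dtype=float) for s in names])
    if mat.ndim != 2 or mat.shape[1] == 0:
        raise ValueError("need per-peak counts for each sample")
    top_n = min(top_n, mat.shape[1])
    combined = mat.sum(axis=0)
    top = np.argsort(-combined, kind="stable")[:top_n]
    totals = mat[:, top].sum(axis=1)
    if (totals <= 0).any():
        bad = names[int(np.argmin(totals))]
        raise ValueError(f"sample {bad!r} has zero reads in common peaks")
    mean_total = totals.mean()
    return ScalingFactors(
        {s: mean_total / t for s, t in zip(names, totals)}, method="common-peak"
    )


def subtract_background(
    control: CoverageTrack,
    ko: CoverageTrack,
    clip_negative: bool = True,
    control_id: str = "control",
    ko_id: str = "ko",
    scaling_method: str = "unspecified",
) -> CorrectedTrack:
    """Control minus KO per bin; negatives clipped to zero unless disabled."""
    if not control.same_grid(ko):
        raise ValueError("control and KO tracks are on different grids")
    data = {}
    for chrom in control.layout:
        diff = control.data[chrom] - ko.data[chrom]
        data[chrom] = np.maximum(diff, 0.0) if clip_negative else diff
    units = "corrected" if clip_negative else "difference"
    track = CoverageTrack(control.layout, control.bin_size, data, units=units)
    return CorrectedTrack(track, control_id, ko_id, scaling_method)


def knockout_correct(
    control: Sequence[CoverageTrack],
    ko: Sequence[CoverageTrack],
    scaling: str = "common-peak",
    spikein_reads: Optional[Mapping[str, int]] = None,
    top_n: int = 10_000,
    peak_z: float = 3.0,
    min_reciprocal: float = 0.25,
    clip_negative: bool = True,
) -> CorrectedTrack:
    """Full knockout-background correction of replicate ChIP tracks.

    Replicates are merged (summed) per condition after per-sample scaling.
    ``scaling="spike-in"`` needs ``spikein_reads`` keyed control_rep1..,
    ko_rep1..; ``"common-peak"`` calls peaks on the merged tracks (runs of
    >= 2 bins above the robust threshold), keeps control peaks reciprocally
    covered by KO peaks (>= ``min_reciprocal`` of their length, so broad
    specific domains touched by a stray KO bin do not count as shared
    background) and equalizes read totals over the top ``top_n`` of them.
    """
    from .zones import threshold_call_peaks   # local import: no cycle at load

    names = [f"control_rep{i+1}" for i in range(len(control))] + [
        f"ko_rep{i+1}" for i in range(len(ko))
    ]
    tracks = dict(zip(names, list(control) + list(ko)))
    if scaling == "spike-in":
        if spikein_reads is None:
            raise ValueError("spike-in scaling requires spikein_reads")
        factors = spikein_scale({n: spikein_reads[n] for n in names})
    elif scaling == "common-peak":
        bs = control[0].bin_size
        merged_c = _sum_tracks(list(control))
        merged_k = _sum_tracks(list(ko))
        peaks_c = threshold_call_peaks(merged_c, peak_z, 2 * bs)
        peaks_k = threshold_call_peaks(merged_k, peak_z, 2 * bs)
        common = peaks_c.subset(overlap_fraction(peaks_c, peaks_k) >= min_reciprocal)
        if len(common) == 0:
            raise ValueError("no common control/KO peaks for scaling")
        counts = {
            n: np.array([t.interval_sum(iv) for iv in common])
            for n, t in tracks.items()
        }
        factors = common_peak_scale(counts, top_n)
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    scaled_c = _sum_tracks([t.scale(factors[n]) for n, t in tracks.items()
                            if n.startswith("control")])
    scaled_k = _sum_tracks([t.scale(factors[n]) for n, t in tracks.items()
                            if n.startswith("ko")])
    return subtract_background(
        scaled_c, scaled_k, clip_negative=clip_negative,
        control_id="+".join(n for n in names if n.startswith("control")),
        ko_id="+".join(n for n in names if n.startswith("ko")),
        scaling_method=factors.method,
    )


def _sum_tracks(tracks: Sequence[CoverageTrack]) -> CoverageTrack:
    data = {
        c: np.sum([t.data[c] for t in tracks], axis=0) for c in tracks[0].layout
    }
    return CoverageTrack(tracks[0].layout, tracks[0].bin_size, data,
                         units=tracks[0].units)


def log2_ratio(
    track_a: CoverageTrack, track_b: CoverageTrack, pseudocount: float = 1.0
) -> CoverageTrack:
    """``log2((a + pc) / (b + pc))`` per bin."""
    if not track_a.same_grid(track_b):
        raise ValueError("tracks are on different grids")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    data = {
        c: np.log2((track_a.data[c] + pseudocount) / (track_b.data[c] + pseudocount))
        for c in track_a.layout
    }
    return CoverageTrack(track_a.layout, track_a.bin_size, data, units="log-ratio")


def genome_fraction_marked(
    corrected: CoverageTrack,
    bin_size: int = 10_000,
    n_hist_bins: int = 100,
    smooth: int = 3,
) -> PositivityResult:
    """Fraction of the genome carrying the mark, from the bimodal histogram
    of per-bin signal.

    The track is re-binned to ``bin_size`` by mean, a histogram of
    log1p(signal) is built (``n_hist_bins`` equal-width bins, moving-average
    smoothed), the two highest-frequency local maxima are located and the
    threshold is set at the minimum-frequency histogram bin strictly between
    them (leftmost on ties). The valley must dip below half the smaller
    mode's height; otherwise (or with a single maximum) the distribution is
    treated as unimodal and a ``ValueError`` is raised.
    """
    track = corrected if corrected.bin_size == bin_size else corrected.rebin(bin_size)
    vals = track.values()
    vals = vals[np.isfinite(vals)]
    logv = np.log1p(vals)
    freq, edges = np.histogram(logv, bins=n_hist_bins)
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        sm = np.convolve(freq, kernel, mode="same")
    else:
        sm = freq.astype(float)
    # local maxima of the smoothed histogram (plateau-safe)
    left = np.concatenate([[-np.inf], sm[:-1]])
    right = np.concatenate([sm[1:], [-np.inf]])
    is_max = (sm > left) & (sm >= right)
    maxima = np.flatnonzero(is_max)
    if maxima.size < 2:
        raise ValueError("no bimodal structure in signal histogram")
    top2 = maxima[np.argsort(-sm[maxima], kind="stable")[:2]]
    lo, hi = sorted(int(i) for i in top2)
    if hi - lo < 2:
        raise ValueError("no bimodal structure in signal histogram")
    between = sm[lo + 1 : hi]
    if between.min() >= 0.5 * min(sm[lo], sm[hi]):
        raise ValueError("no bimodal structure in signal histogram")
    t_idx = lo + 1 + int(np.argmin(between))
    threshold = 0.5 * (edges[t_idx] + edges[t_idx + 1])
    fraction = 100.0 * float(np.mean(logv > threshold))
    return PositivityResult(
        threshold=float(threshold),
        fraction_marked=fraction,
        bin_edges=edges,
        frequencies=freq,
        n_bins=logv.size,
    )


def compartment_signal(
    track: CoverageTrack,
    compartments_a: IntervalSet,
    compartments_b: IntervalSet,
    bin_size: int = 50_000,
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Per-compartment signal distributions and a two-sided rank-sum p-value.

    Each ``bin_size`` bin is assigned to the compartment covering the
    majority of it; bins touching neither are dropped. Returns
    ``(a_values, b_values, p_value)``.
    """
    for a in compartments_a:
        for b in (x for x in compartments_b if x.chrom == a.chrom):
            if a.start < b.end and b.start < a.end:
                raise ValueError("A and B compartments overlap")
    binned = track if track.bin_size == bin_size else track.rebin(bin_size)

    def _coverage(comp: IntervalSet) -> Dict[str, np.ndarray]:
        cov = {c: np.zeros(binned.layout.n_bins(c, bin_size)) for c in binned.layout}
        for iv in comp:
            b0 = iv.start // bin_size
            b1 = -(-iv.end // bin_size)
            for b in range(b0, b1):
                lo = max(iv.start, b * bin_size)
                hi = min(iv.end, (b + 1) * bin_size)
                cov[iv.chrom][b] += hi - lo
        return cov

    cov_a, cov_b = _coverage(compartments_a), _coverage(compartments_b)
    a_vals, b_vals = [], []
    for chrom in binned.layout:
        vals = binned.data[chrom]
        ca, cb = cov_a[chrom], cov_b[chrom]
        any_cov = (ca > 0) | (cb > 0)
        to_a = any_cov & (ca >= cb)
        to_b = any_cov & (cb > ca)
        a_vals.append(vals[to_a])
        b_vals.append(vals[to_b])
    a_arr = np.concatenate(a_vals)
    b_arr = np.concatenate(b_vals)
    a_arr = a_arr[np.isfinite(a_arr)]
    b_arr = b_arr[np.isfinite(b_arr)]
    p = float(stats.ranksums(a_arr, b_arr).pvalue)
    return a_arr, b_arr, p


def gene_quartile_signal(
    track: CoverageTrack,
    genes: IntervalSet,
    expression: Sequence[float],
) -> Tuple[List[np.ndarray], float]:
    """Gene-body signal split by expression quartile, normalized to the
    median of the top quartile.

    Returns ``(per-quartile normalized value arrays, low->high, p)`` with p
    from a Kruskal-Wallis one-way location test across quartiles.
    """
    if len(genes) < 8:
        raise ValueError("need at least 8 genes for quartiles")
    expr = np.asarray(expression, dtype=float)
    if expr.shape != (len(genes),):
        raise ValueError("need one expression value per gene")
    missing = np.flatnonzero(~np.isfinite(expr))
    if missing.size:
        names = [genes[int(i)].name for i in missing[:5]]
        raise ValueError(f"missing expression value for genes: {names}")
    # per-gene body signal density (mean signal per bp ~ RPKM-like)
    signal = np.array([track.interval_mean(g) for g in genes])
    quart = np.searchsorted(
        np.quantile(expr, [0.25, 0.5, 0.75]), expr, side="right"
    )
    top_median = np.median(signal[quart == 3])
    if top_median == 0:
        raise ValueError("top quartile has zero median signal")
    norm = signal / top_median
    groups = [norm[quart == q] for q in range(4)]
    p = float(stats.kruskal(*groups).pvalue)
    return groups, p


def profile_similarity(
    profiles: Mapping[str, np.ndarray],
) -> Tuple[List[str], np.ndarray, Optional[np.ndarray]]:
    """Spearman correlation matrix between mean profile vectors plus
    average-linkage clustering on 1 - rho.

    Constant (zero-variance) profiles get NaN correlations and are left out
    of the clustering. Returns ``(labels, rho_matrix, linkage or None)``.
    """
    labels = list(profiles)
    vecs = [np.asarray(profiles[k], dtype=float) for k in labels]
    n_len = {v.size for v in vecs}
    if len(n_len) != 1:
        raise ValueError("profiles must have equal length")
    n = len(labels)
    rho = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            if np.ptp(vecs[i]) == 0 or np.ptp(vecs[j]) == 0:
                r = np.nan
            else:
                r = stats.spearmanr(vecs[i], vecs[j]).statistic
            rho[i, j] = rho[j, i] = r
    usable = [i for i in range(n) if not np.isnan(np.delete(rho[i], i)).any()]
    link = None
    if len(usable) >= 2:
        sub = rho[np.ix_(usable, usable)]
        dist = squareform(1.0 - sub, checks=False)
        link = linkage(dist, method="average")
    return labels, rho, link
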