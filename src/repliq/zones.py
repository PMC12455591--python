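"""Replication initiation-zone calling, differential classification and
permutation enrichment.

Zones are broad regions of clustered replication origins called from
nascent-DNA (EdU-HU) coverage: peaks from every sample are combined, merged
within 10 kb and kept at >= 20 kb. Differential zones between conditions are
gated on concentration (log2 normalized mean count), |log2FC| and FDR, and
feature enrichment at the activated class is assessed by resampling
zone-sized regions from a background set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genomic import (
    CoverageTrack,
    GenomicInterval,
    IntervalSet,
    central_window,
    count_overlaps,
    filter_min_length,
    merge_within,
    metaprofile,
)

__all__ = [
    "EnrichmentResult",
    "threshold_call_peaks",
    "call_zones",
    "count_reads_in_intervals",
    "zone_statistics",
    "classify_zones",
    "hyperactivation_test",
    "permutation_enrichment",
    "zone_gene_abundance",
    "zone_summits",
    "fork_progression",
]


@dataclass
class EnrichmentResult:
    """Permutation-test summary for feature overlap at a query set."""

    observed: float
    null_mean: float
    null_sd: float
    z: float                     # NaN when the null has zero spread
    p_value: float               # one-sided (enrichment), +1 corrected
    n_permutations: int
    seed: Optional[int]


def threshold_call_peaks(
    track: CoverageTrack, z: float = 3.0, min_run: int = 5_000
) -> IntervalSet:
    """Call peaks as maximal runs of bins above a robust global threshold.

    The threshold is ``median + z * 1.4826 * MAD`` over all genome bins;
    runs shorter than ``min_run`` bp are dropped. A flat or all-zero track
    yields an empty set.
    """
    allv = track.values()
    allv = allv[np.isfinite(allv)]
    med = np.median(allv)
    mad = np.median(np.abs(allv - med))
    threshold = med + z * 1.4826 * mad
    out = []
    bs = track.bin_size
    for chrom in track.layout:
        above = track.data[chrom] > threshold
        edges = np.flatnonzero(np.diff(np.concatenate([[0], above.view(np.int8), [0]])))
        for b0, b1 in zip(edges[::2], edges[1::2]):
            start = int(b0) * bs
            end = min(int(b1) * bs, track.layout[chrom])
            if end - start >= min_run:
                out.append(GenomicInterval(chrom, start, end))
    return IntervalSet(out)


def call_zones(
    peak_sets: Sequence[IntervalSet],
    merge_gap: int = 10_000,
    min_size: int = 20_000,
) -> IntervalSet:
    """Comprehensive zone list: union of peaks called in any sample, merged
    within ``merge_gap``, kept at >= ``min_size``."""
    if not peak_sets:
        raise ValueError("need at least one peak set")
    combined = peak_sets[0].union(*peak_sets[1:])
    if len(combined) == 0:
        return combined
    zones = filter_min_length(merge_within(combined, merge_gap), min_size)
    named = [
        GenomicInterval(iv.chrom, iv.start, iv.end, f"zone_{i:04d}")
        for i, iv in enumerate(zones)
    ]
    return IntervalSet(named)


def count_reads_in_intervals(
    intervals: IntervalSet, tracks: Mapping[str, CoverageTrack]
) -> pd.DataFrame:
    """Summed coverage per interval per sample (columns = sample names)."""
    data = {
        sample: [track.interval_sum(iv) for iv in intervals]
        for sample, track in tracks.items()
    }
    df = pd.DataFrame(data)
    df.insert(0, "chrom", [iv.chrom for iv in intervals])
    df.insert(1, "start", [iv.start for iv in intervals])
    df.insert(2, "end", [iv.end for iv in intervals])
    df.insert(3, "name", [iv.name for iv in intervals])
    return df


def zone_statistics(
    zones: IntervalSet,
    counts: pd.DataFrame,
    design: Mapping[str, str],
    control: str = "control",
    treatment: str = "ko",
    lib_sizes: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """Per-zone concentration, log2 fold change, p-value and FDR.

    ``counts`` holds one column per sample (as from
    :func:`count_reads_in_intervals`); ``design`` maps sample -> condition.
    Counts are normalized to the mean library size; concentration is
    ``log2(mean normalized count + 1)`` per condition and the fold change is
    their difference (treatment minus control). With < 3 replicates per
    condition the p-value comes from the exact conditional binomial test of
    a Poisson rate ratio on pooled raw counts; with >= 3 replicates a Welch
    t-test on log2 normalized counts is used. FDR is Benjamini-Hochberg over
    zones; zones with zero counts everywhere get missing statistics.
    """
    samples = [s for s in counts.columns if s in design]
    ctrl_s = [s for s in samples if design[s] == control]
    trt_s = [s for s in samples if design[s] == treatment]
    if not ctrl_s or not trt_s:
        raise ValueError("need at least one replicate per condition")
    if lib_sizes is None:
        lib_sizes = {s: float(counts[s].sum()) for s in samples}
    mean_lib = np.mean([lib_sizes[s] for s in samples])
    norm = {s: counts[s].to_numpy(dtype=float) * (mean_lib / lib_sizes[s])
            for s in samples}
    raw = {s: counts[s].to_numpy(dtype=float) for s in samples}

    n_zones = len(counts)
    conc_c = np.log2(np.mean([norm[s] for s in ctrl_s], axis=0) + 1.0)
    conc_t = np.log2(np.mean([norm[s] for s in trt_s], axis=0) + 1.0)
    lfc = conc_t - conc_c

    total = np.sum([raw[s] for s in samples], axis=0)
    nonzero = total > 0
    pvals = np.full(n_zones, np.nan)
    use_welch = len(ctrl_s) >= 3 and len(trt_s) >= 3
    if use_welch:
        log_c = np.log2(np.array([norm[s] for s in ctrl_s]) + 1.0)
        log_t = np.log2(np.array([norm[s] for s in trt_s]) + 1.0)
        res = stats.ttest_ind(log_t, log_c, axis=0, equal_var=False)
        pvals = np.asarray(res.pvalue)
    else:
        k_c = np.sum([raw[s] for s in ctrl_s], axis=0)
        k_t = np.sum([raw[s] for s in trt_s], axis=0)
        l_c = sum(lib_sizes[s] for s in ctrl_s)
        l_t = sum(lib_sizes[s] for s in trt_s)
        p0 = l_t / (l_c + l_t)
        for i in range(n_zones):
            if not nonzero[i]:
                continue
            k = int(round(k_t[i]))
            n = int(round(k_t[i] + k_c[i]))
            pvals[i] = stats.binomtest(k, n, p0, alternative="two-sided").pvalue
    pvals = np.where(nonzero, pvals, np.nan)

    fdr = np.full(n_zones, np.nan)
    tested = np.isfinite(pvals)
    if tested.any():
        fdr[tested] = multipletests(pvals[tested], method="fdr_bh")[1]

    out = counts[["chrom", "start", "end", "name"]].copy()
    out[f"conc_{control}"] = np.where(nonzero, conc_c, np.nan)
    out[f"conc_{treatment}"] = np.where(nonzero, conc_t, np.nan)
    out["lfc"] = np.where(nonzero, lfc, np.nan)
    out["pvalue"] = pvals
    out["fdr"] = fdr
    return out


def classify_zones(
    statistics: pd.DataFrame,
    conc_min: float = 7.0,
    lfc_min: float = 0.7,
    fdr_max: float = 1e-10,
) -> pd.DataFrame:
    """Assign {activated, deactivated, constitutive} per zone.

    Differential calls require the concentration gate (>= ``conc_min`` in at
    least one condition), ``|log2FC| >= lfc_min`` and ``FDR <= fdr_max``.
    """
    conc_cols = [c for c in statistics.columns if c.startswith("conc_")]
    conc_max = statistics[conc_cols].max(axis=1)
    lfc = statistics["lfc"]
    fdr = statistics["fdr"]
    gates = (conc_max >= conc_min) & (fdr <= fdr_max)
    cls = np.where(
        gates & (lfc >= lfc_min),
        "activated",
        np.where(gates & (lfc <= -lfc_min), "deactivated", "constitutive"),
    )
    out = statistics.copy()
    out["class"] = cls
    return out


def hyperactivation_test(
    control_counts: Sequence[float],
    treatment_counts: Sequence[float],
    alternative: str = "greater",
) -> Tuple[float, float]:
    """Paired Wilcoxon signed-rank test of per-zone normalized counts
    (treatment vs control over the same zones). Returns (statistic, p)."""
    res = stats.wilcoxon(
        np.asarray(treatment_counts, dtype=float),
        np.asarray(control_counts, dtype=float),
        alternative=alternative,
    )
    return float(res.statistic), float(res.pvalue)


def _total_overlaps(query: IntervalSet, features: IntervalSet) -> int:
    return int(count_overlaps(query, features).sum())


def permutation_enrichment(
    query: IntervalSet,
    features: IntervalSet,
    background: Optional[IntervalSet] = None,
    n: int = 5_000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    mode: str = "background",
    layout=None,
) -> EnrichmentResult:
    """Permutation test of feature overlap at the query regions.

    Observed statistic: total number of features overlapping query regions.
    ``mode="background"`` draws |query| regions from ``background`` without
    replacement for each of ``n`` permutations (the query must be drawn from
    the same universe); ``mode="genome"`` places |query| length-matched
    regions uniformly on the genome (requires ``layout``). The one-sided
    enrichment p-value carries the +1 correction, so the smallest attainable
    p is 1/(n+1).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    observed = _total_overlaps(query, features)
    nq = len(query)
    if nq == 0:
        raise ValueError("empty query set")

    if mode == "background":
        if background is None:
            raise ValueError("background mode requires a background set")
        nb = len(background)
        if nb < nq:
            raise ValueError("background must be at least as large as the query")
        per_bg = count_overlaps(background, features)
        null = np.empty(n)
        for i in range(n):
            idx = rng.choice(nb, size=nq, replace=False)
            null[i] = per_bg[idx].sum()
    elif mode == "genome":
        if layout is None:
            raise ValueError("genome mode requires a layout")
        chroms = list(layout)
        weights = np.array([layout[c] for c in chroms], dtype=float)
        weights /= weights.sum()
        lengths = np.array([len(iv) for iv in query])
        feat = features.by_chrom()
        starts = {c: np.array([iv.start for iv in ivs]) for c, ivs in feat.items()}
        ends = {c: np.sort([iv.end for iv in ivs]) for c, ivs in feat.items()}
        null = np.empty(n)
        for i in range(n):
            tot = 0
            cidx = rng.choice(len(chroms), size=nq, p=weights)
            offs = rng.random(nq)
            for j in range(nq):
                chrom = chroms[cidx[j]]
                clen = layout[chrom]
                w = min(lengths[j], clen)
                s = int(offs[j] * (clen - w + 1))
                if chrom in starts:
                    tot += int(
                        np.searchsorted(starts[chrom], s + w, side="left")
                        - np.searchsorted(ends[chrom], s, side="right")
                    )
            null[i] = tot
    else:
        raise ValueError(f"unknown mode {mode!r}")

    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1)) if n > 1 else 0.0
    z = (observed - null_mean) / null_sd if null_sd > 0 else float("nan")
    p = (1.0 + float(np.sum(null >= observed))) / (n + 1.0)
    return EnrichmentResult(
        observed=float(observed),
        null_mean=null_mean,
        null_sd=null_sd,
        z=float(z),
        p_value=float(p),
        n_permutations=n,
        seed=seed,
    )


def zone_gene_abundance(
    zones_by_class: Mapping[str, IntervalSet],
    genes: IntervalSet,
    layout,
    width: int = 50_000,
) -> Dict[str, float]:
    """Mean number of genes overlapping the central ``width`` window of each
    zone, per class (size-controlled gene abundance)."""
    out = {}
    for cls, zones in zones_by_class.items():
        if len(zones) == 0:
            out[cls] = float("nan")
            continue
        windows = IntervalSet(central_window(iv, width, layout) for iv in zones)
        out[cls] = float(count_overlaps(windows, genes).mean())
    return out


def zone_summits(track: CoverageTrack, zones: IntervalSet) -> IntervalSet:
    """1 bp summit (center of the maximal-signal bin) per zone."""
    out = []
    bs = track.bin_size
    for iv in zones:
        arr = track.data[iv.chrom]
        b0, b1 = iv.start // bs, -(-iv.end // bs)
        b = b0 + int(np.argmax(arr[b0:b1]))
        pos = b * bs + bs // 2
        out.append(GenomicInterval(iv.chrom, pos, pos + 1, iv.name))
    return IntervalSet(out)


def fork_progression(
    tracks: Mapping[str, CoverageTrack],
    summits: IntervalSet,
    window: int = 200_000,
) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    """Mean +- SE nascent-DNA profiles around core initiation summits per
    condition; displacement of signal away from the summit tracks fork
    progression."""
    out = {}
    for cond, track in tracks.items():
        _, mean, se = metaprofile(track, summits, window, window, "point-centered")
        out[cond] = (mean, se)
    return out
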