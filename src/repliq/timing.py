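"""Replication-timing index (RTI) analysis from early/late S-phase counts.

Each 50 kb bin gets an RTI in [-1 (late), +1 (early)] per replicate and
condition: ``(e - l) / (e + l)`` on depth-normalized early/late counts, with
no quantile normalization so global differences are preserved. Differential
bins (|dRTI| above a gate plus an FDR gate on a per-bin Welch test across
replicates) merge into regions, which are classified as anticipated/delayed
and tested for overlap with early/late transition areas.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .chip import log2_ratio
from .genomic import CoverageTrack, GenomicInterval, IntervalSet

logger = logging.getLogger(__name__)

__all__ = [
    "RTRegion",
    "rti",
    "rti_track",
    "rt_log2_track",
    "differential_rt",
    "merge_rt_regions",
    "transition_classify",
    "element_rt",
    "global_rt_compare",
    "GlobalRTComparison",
]


def rti(early, late, early_factor: float = 1.0, late_factor: float = 1.0):
    """Replication timing index ``(e - l) / (e + l)`` on depth-normalized
    counts; exactly +1 when late is 0, -1 when early is 0, NaN when both
    are 0. Accepts scalars or arrays."""
    e = np.asarray(early, dtype=float) * early_factor
    l = np.asarray(late, dtype=float) * late_factor
    total = e + l
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, (e - l) / np.where(total > 0, total, 1.0), np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def rti_track(
    early: CoverageTrack, late: CoverageTrack, depth_normalize: bool = True
) -> CoverageTrack:
    """Per-bin RTI track from early/late count tracks.

    With ``depth_normalize`` the two fractions are first scaled to equal
    total counts (the package's depth normalization; no quantile step).
    """
    if not early.same_grid(late):
        raise ValueError("early and late tracks are on different grids")
    fe = fl = 1.0
    if depth_normalize:
        te = float(np.nansum(early.values()))
        tl = float(np.nansum(late.values()))
        if te <= 0 or tl <= 0:
            raise ValueError("cannot depth-normalize a zero-count fraction")
        mean_t = 0.5 * (te + tl)
        fe, fl = mean_t / te, mean_t / tl
    data = {
        c: rti(early.data[c], late.data[c], fe, fl) for c in early.layout
    }
    return CoverageTrack(early.layout, early.bin_size, data, units="rti")


def rt_log2_track(
    early: CoverageTrack, late: CoverageTrack, pseudocount: float = 1.0
) -> CoverageTrack:
    """log2 early/late track for browsing; sign agrees with the RTI."""
    return log2_ratio(early, late, pseudocount)


def _stack(tracks: Sequence[CoverageTrack]) -> np.ndarray:
    return np.vstack([t.values() for t in tracks])


def differential_rt(
    control: Sequence[CoverageTrack],
    ko: Sequence[CoverageTrack],
    drti_min: float = 0.2,
    fdr_max: float = 0.01,
    delta_only: bool = False,
) -> pd.DataFrame:
    """Flag differential-timing bins between conditions.

    ``control``/``ko`` are per-replicate RTI tracks on a common grid. A bin
    is flagged iff ``|dRTI| > drti_min`` and its Benjamini-Hochberg FDR from
    a per-bin two-sided t-test across replicate RTIs is ``< fdr_max``. With
    >= 3 replicates per condition the test is Welch's; with exactly 2 the
    pooled-variance t-test is used instead, because the Welch-Satterthwaite
    degrees of freedom collapse toward 1 (a near-Cauchy null with no power)
    whenever one condition's replicates agree closely. Bins with a missing
    RTI in any replicate are excluded from testing. With a single replicate
    per condition the test is impossible: request ``delta_only=True`` to
    gate on dRTI alone.
    """
    layout = control[0].layout
    bs = control[0].bin_size
    for t in list(control) + list(ko):
        if not t.same_grid(control[0]):
            raise ValueError("RTI tracks are on different grids")
    if (len(control) < 2 or len(ko) < 2) and not delta_only:
        raise ValueError(
            "need >= 2 replicates per condition for the FDR test; "
            "pass delta_only=True to gate on dRTI alone"
        )
    mc = _stack(control)
    mk = _stack(ko)
    ok = np.isfinite(mc).all(axis=0) & np.isfinite(mk).all(axis=0)
    mean_c = np.nanmean(mc, axis=0)
    mean_k = np.nanmean(mk, axis=0)
    drti = mean_k - mean_c

    n = mc.shape[1]
    pvals = np.full(n, np.nan)
    fdr = np.full(n, np.nan)
    if not delta_only:
        welch = len(control) >= 3 and len(ko) >= 3
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.ttest_ind(
                mk[:, ok], mc[:, ok], axis=0, equal_var=not welch
            )
        p = np.asarray(res.pvalue)
        # degenerate bins with zero variance in both conditions
        degen = np.isnan(p)
        d = drti[ok]
        p[degen & (d == 0)] = 1.0
        p[degen & (d != 0)] = 0.0
        pvals[ok] = p
        fdr_ok = multipletests(p, method="fdr_bh")[1]
        fdr[ok] = fdr_ok
        flagged = ok & (np.abs(drti) > drti_min) & (fdr < fdr_max)
    else:
        flagged = ok & (np.abs(drti) > drti_min)

    rows = []
    for chrom in layout:
        nb = layout.n_bins(chrom, bs)
        for b in range(nb):
            rows.append((chrom, b * bs, min((b + 1) * bs, layout[chrom])))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["rti_control"] = mean_c
    df["rti_ko"] = mean_k
    df["drti"] = drti
    df["pvalue"] = pvals
    df["fdr"] = fdr
    df["flagged"] = flagged
    return df


@dataclass
class RTRegion:
    """Maximal run of adjacent same-direction differential bins."""

    chrom: str
    start: int
    end: int
    direction: str               # "anticipated" (KO earlier) | "delayed"
    mean_drti: float
    n_bins: int
    transition: Optional[bool] = None

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end,
                               self.direction, self.mean_drti)


def merge_rt_regions(bins: pd.DataFrame) -> List[RTRegion]:
    """Merge adjacent flagged bins with the same dRTI sign into regions."""
    flagged = bins[bins["flagged"]].sort_values(["chrom", "start"])
    regions: List[RTRegion] = []
    cur: Optional[dict] = None
    for row in flagged.itertuples():
        sign = 1 if row.drti > 0 else -1
        if (
            cur is not None
            and row.chrom == cur["chrom"]
            and row.start == cur["end"]
            and sign == cur["sign"]
        ):
            cur["end"] = row.end
            cur["drtis"].append(row.drti)
        else:
            if cur is not None:
                regions.append(_finish_region(cur))
            cur = {"chrom": row.chrom, "start": row.start, "end": row.end,
                   "sign": sign, "drtis": [row.drti]}
    if cur is not None:
        regions.append(_finish_region(cur))
    return regions


def _finish_region(cur: dict) -> RTRegion:
    mean_drti = float(np.mean(cur["drtis"]))
    return RTRegion(
        chrom=cur["chrom"],
        start=cur["start"],
        end=cur["end"],
        direction="anticipated" if mean_drti > 0 else "delayed",
        mean_drti=mean_drti,
        n_bins=len(cur["drtis"]),
    )


def transition_classify(region: RTRegion, control_rti: CoverageTrack) -> bool:
    """Whether a differential region sits in an early/late transition area.

    Compares the control RTI one bin upstream, at the region-center bin and
    one bin downstream: strictly monotone (increasing or decreasing) means
    the region is part of a transition. Regions whose flanking bins fall off
    the chromosome are classified False with a warning.
    """
    bs = control_rti.bin_size
    arr = control_rti.data[region.chrom]
    center_bin = ((region.start + region.end) // 2) // bs
    up, down = center_bin - 1, center_bin + 1
    if up < 0 or down >= arr.size:
        logger.warning(
            "region %s:%d-%d at chromosome edge; transition set to False",
            region.chrom, region.start, region.end,
        )
        return False
    a, b, c = arr[up], arr[center_bin], arr[down]
    if np.isnan([a, b, c]).any():
        return False
    return bool((a < b < c) or (a > b > c))


def element_rt(
    elements: IntervalSet,
    early: CoverageTrack,
    late: CoverageTrack,
    mode: str = "regional",
    window: int = 50_000,
    pseudocount: float = 1.0,
) -> np.ndarray:
    """Replication timing (log2 early/late) per annotated element.

    ``regional`` uses counts in the ``window`` bp region surrounding each
    element midpoint; ``local`` uses only counts overlapping the element
    (NaN when an element has zero total counts).
    """
    if not early.same_grid(late):
        raise ValueError("early and late tracks are on different grids")
    out = np.empty(len(elements))
    for i, iv in enumerate(elements):
        if mode == "regional":
            mid = iv.midpoint
            chrom_len = early.layout[iv.chrom]
            s = max(0, mid - window // 2)
            e = min(chrom_len, s + window)
            region = GenomicInterval(iv.chrom, s, e)
            ce = early.interval_sum(region)
            cl = late.interval_sum(region)
        elif mode == "local":
            ce = early.interval_sum(iv)
            cl = late.interval_sum(iv)
            if ce + cl == 0:
                out[i] = np.nan
                continue
        else:
            raise ValueError(f"unknown mode {mode!r}")
        out[i] = np.log2((ce + pseudocount) / (cl + pseudocount))
    return out


@dataclass
class GlobalRTComparison:
    """Genome-wide control-vs-KO RTI relationship."""

    table: pd.DataFrame          # columns: control, ko (one row per usable bin)
    slope: float                 # total-least-squares through the origin
    early_mean_control: float
    early_mean_ko: float
    late_mean_control: float
    late_mean_ko: float


def global_rt_compare(
    control_rti: CoverageTrack, ko_rti: CoverageTrack
) -> GlobalRTComparison:
    """Scatter of per-bin RTIs and a flattening statistic.

    The flattening statistic is the slope of the total-least-squares line
    through the origin fit to (control, KO) RTI pairs; a slope below 1 means
    the KO program is compressed toward the middle line. Early/late halves
    (by the sign of the control RTI) are summarized separately. Bins missing
    in either condition are dropped.
    """
    if not control_rti.same_grid(ko_rti):
        raise ValueError("RTI tracks are on different grids")
    x = control_rti.values()
    y = ko_rti.values()
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    sxx = float(np.sum(x * x))
    syy = float(np.sum(y * y))
    sxy = float(np.sum(x * y))
    if sxy == 0:
        slope = float("nan")
    else:
        slope = (syy - sxx + np.hypot(syy - sxx, 2 * sxy)) / (2 * sxy)
    early = x > 0
    late = x < 0
    return GlobalRTComparison(
        table=pd.DataFrame({"control": x, "ko": y}),
        slope=slope,
        early_mean_control=float(np.mean(x[early])) if early.any() else float("nan"),
        early_mean_ko=float(np.mean(y[early])) if early.any() else float("nan"),
        late_mean_control=float(np.mean(x[late])) if late.any() else float("nan"),
        late_mean_ko=float(np.mean(y[late])) if late.any() else float("nan"),
    )
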