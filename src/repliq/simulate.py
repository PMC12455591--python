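"""Planted-truth simulator for the full analysis pipeline.

The generator emulates the data-generating assumptions of the study design:

* a miniature genome (default 2 x 20 Mb) with alternating early/late
  replication domains that double as A/B compartments;
* quantitative ChIP of a broad histone mark (H4K16ac-like) where control and
  knockout libraries share promoter-like *nonspecific* peaks, with per-sample
  spike-in read counts, so knockout-background correction can be tested;
* nascent-DNA (EdU-HU) coverage containing constitutive initiation zones in
  early domains, knockout-hyperactivated zones (strongest half), knockout-only
  de novo zones over LTR clusters in late domains, and a few deactivated
  zones;
* early/late REPLI-seq counts per 50 kb bin drawn from a latent replication
  timing program in [-1, 1] that the knockout flattens globally and
  anticipates locally at activated LTRs;
* genome sequence whose LTR bodies are AT-depleted, flanked by AT-rich
  regions carrying strand-asymmetric poly(dA)/poly(dT) tracts.

Every random draw flows from one seed; the returned :class:`SyntheticTruth`
records what was planted so recovery can be scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .config import SyntheticConfig
from .genomic import (
    CoverageTrack,
    GenomeLayout,
    GenomicInterval,
    IntervalSet,
    count_overlaps,
)

__all__ = [
    "SyntheticTruth",
    "GenomeSim",
    "ChipSim",
    "simulate_genome",
    "simulate_chip",
    "simulate_eduhu",
    "simulate_repliseq",
    "simulate_study",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_A, _C, _G, _T = 0, 1, 2, 3

EDU_CONDITIONS = ("control", "ko", "cmyc")


@dataclass
class SyntheticTruth:
    """Ground truth planted by :func:`simulate_genome`."""

    layout: GenomeLayout
    compartments_a: IntervalSet
    compartments_b: IntervalSet
    genes: IntervalSet
    gene_expression: np.ndarray           # aligned with genes order
    te_catalog: IntervalSet               # names "CLASS|id", stranded
    activated_ltrs: IntervalSet           # subset of the LTR class
    nonspecific_peaks: IntervalSet
    marked: IntervalSet                   # true specific-signal domains
    marked_fraction: float
    specific_chip: CoverageTrack          # true specific rate per coverage bin
    constitutive_zones: IntervalSet       # score = plateau amplitude
    hyper_zone_names: frozenset           # strongest half (hyperactivated in KO)
    denovo_zones: IntervalSet
    deactivated_zones: IntervalSet        # score = amplitude (reduced in KO)
    rt_program: Dict[str, Dict[str, np.ndarray]]   # condition -> chrom -> RTI
    rt_bin: int

    def ltrs(self) -> IntervalSet:
        return IntervalSet(
            iv for iv in self.te_catalog if iv.name.startswith("LTR|")
        )

    def sines(self) -> IntervalSet:
        return IntervalSet(
            iv for iv in self.te_catalog if iv.name.startswith("SINE|")
        )

    def anticipated_bin_mask(self) -> Dict[str, np.ndarray]:
        """Boolean mask per chromosome of 50 kb bins overlapping activated
        LTRs (the bins whose KO timing program is shifted early)."""
        masks = {}
        ltr_by_chrom = self.activated_ltrs.by_chrom()
        for chrom in self.layout:
            n = self.layout.n_bins(chrom, self.rt_bin)
            mask = np.zeros(n, dtype=bool)
            for iv in ltr_by_chrom.get(chrom, []):
                mask[iv.start // self.rt_bin : (iv.end - 1) // self.rt_bin + 1] = True
            masks[chrom] = mask
        return masks

    def all_zones(self) -> IntervalSet:
        return self.constitutive_zones.union(
            self.denovo_zones, self.deactivated_zones
        )

    def to_json(self, path) -> None:
        def ivs(s: IntervalSet):
            return [
                [iv.chrom, iv.start, iv.end, iv.name, iv.score, iv.strand]
                for iv in s
            ]

        payload = {
            "layout": dict(self.layout.items()),
            "marked_fraction": self.marked_fraction,
            "compartments_a": ivs(self.compartments_a),
            "compartments_b": ivs(self.compartments_b),
            "genes": ivs(self.genes),
            "gene_expression": self.gene_expression.tolist(),
            "te_catalog": ivs(self.te_catalog),
            "activated_ltrs": ivs(self.activated_ltrs),
            "nonspecific_peaks": ivs(self.nonspecific_peaks),
            "marked": ivs(self.marked),
            "constitutive_zones": ivs(self.constitutive_zones),
            "hyper_zone_names": sorted(self.hyper_zone_names),
            "denovo_zones": ivs(self.denovo_zones),
            "deactivated_zones": ivs(self.deactivated_zones),
            "rt_bin": self.rt_bin,
            "rt_program": {
                cond: {c: arr.tolist() for c, arr in per.items()}
                for cond, per in self.rt_program.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)
            fh.write("\n")


@dataclass
class GenomeSim:
    layout: GenomeLayout
    sequence: Dict[str, str]
    truth: SyntheticTruth


@dataclass
class ChipSim:
    control: List[CoverageTrack]
    ko: List[CoverageTrack]
    spikein: Dict[str, int]               # sample name -> spike-in reads

    def samples(self) -> Dict[str, CoverageTrack]:
        out = {}
        for i, t in enumerate(self.control, 1):
            out[f"control_rep{i}"] = t
        for i, t in enumerate(self.ko, 1):
            out[f"ko_rep{i}"] = t
        return out


# ---------------------------------------------------------------------------
# genome / annotation / sequence


def _domains(layout: GenomeLayout, domain_size: int) -> Tuple[IntervalSet, IntervalSet]:
    """Alternating A (early) / B (late) domains, A first on every chromosome."""
    a, b = [], []
    for chrom in layout:
        length = layout[chrom]
        pos, is_a = 0, True
        while pos < length:
            end = min(pos + domain_size, length)
            (a if is_a else b).append(GenomicInterval(chrom, pos, end))
            pos, is_a = end, not is_a
    return IntervalSet(a), IntervalSet(b)


def _latent_rt(cfg: SyntheticConfig, layout: GenomeLayout) -> Dict[str, np.ndarray]:
    """Sinusoidal latent timing program aligned with the A/B domains:
    positive (early) over A, negative (late) over B, period 2 domains."""
    out = {}
    for chrom in layout:
        n = layout.n_bins(chrom, cfg.rt_bin)
        centers = (np.arange(n) + 0.5) * cfg.rt_bin
        out[chrom] = cfg.rt_amplitude * np.sin(
            np.pi * centers / cfg.domain_size
        )
    return out


class _Reservations:
    """Greedy non-overlap bookkeeping for element placement."""

    def __init__(self):
        self.by_chrom: Dict[str, List[Tuple[int, int]]] = {}

    def conflicts(self, chrom: str, start: int, end: int) -> bool:
        return any(s < end and start < e for s, e in self.by_chrom.get(chrom, []))

    def add(self, chrom: str, start: int, end: int) -> None:
        self.by_chrom.setdefault(chrom, []).append((start, end))


class _SegmentPool:
    """Free-segment allocator: places fixed-width blocks without overlap by
    carving them out of an explicit free list (robust at high packing
    density where rejection sampling stalls)."""

    def __init__(self, segments: List[GenomicInterval]):
        self.segments: List[Tuple[str, int, int]] = [
            (iv.chrom, iv.start, iv.end) for iv in segments
        ]

    def place(self, rng, width: int, grid: int = 1) -> Tuple[str, int]:
        fits = [i for i, (_, s, e) in enumerate(self.segments) if e - s >= width]
        if not fits:
            raise ValueError("layout too small to place requested zones")
        slack = np.array(
            [self.segments[i][2] - self.segments[i][1] - width + 1 for i in fits],
            dtype=float,
        )
        i = fits[int(rng.choice(len(fits), p=slack / slack.sum()))]
        chrom, s, e = self.segments.pop(i)
        start = (s + int(rng.integers(0, e - s - width + 1))) // grid * grid
        start = max(s, start)
        if start > s:
            self.segments.append((chrom, s, start))
        if start + width < e:
            self.segments.append((chrom, start + width, e))
        return chrom, start


def _pick_chrom(rng, layout: GenomeLayout) -> str:
    chroms = list(layout)
    weights = np.array([layout[c] for c in chroms], dtype=float)
    return chroms[rng.choice(len(chroms), p=weights / weights.sum())]


def _place_in_domains(
    rng,
    layout: GenomeLayout,
    domains: Dict[str, List[GenomicInterval]],
    width: int,
    reservations: _Reservations,
    margin: int = 0,
    grid: int = 1,
    max_tries: int = 2000,
) -> Optional[GenomicInterval]:
    for _ in range(max_tries):
        chrom = _pick_chrom(rng, layout)
        doms = [d for d in domains.get(chrom, []) if len(d) >= width + 2 * margin]
        if not doms:
            continue
        dom = doms[rng.integers(len(doms))]
        lo, hi = dom.start + margin, dom.end - margin - width
        if hi < lo:
            continue
        start = int(rng.integers(lo, hi + 1)) // grid * grid
        if reservations.conflicts(chrom, start, start + width):
            continue
        reservations.add(chrom, start, start + width)
        return GenomicInterval(chrom, start, start + width)
    return None


def _random_base_segment(rng, n: int, at_fraction: float) -> np.ndarray:
    p_at = at_fraction / 2.0
    p_gc = (1.0 - at_fraction) / 2.0
    return rng.choice(
        np.array([_A, _C, _G, _T]), size=n, p=[p_at, p_gc, p_gc, p_at]
    ).astype(np.uint8)


def _tract(rng, n: int, base: int) -> np.ndarray:
    """A poly-tract of base ``base`` with a guaranteed >= 75% purity in every
    20-mer: every 8th position carries a different base, the rest the target.
    """
    arr = np.full(n, base, dtype=np.uint8)
    others = np.array([b for b in range(4) if b != base], dtype=np.uint8)
    idx = np.arange(7, n, 8)
    arr[idx] = rng.choice(others, size=idx.size)
    return arr


def simulate_genome(
    config: Optional[SyntheticConfig] = None, rng: Optional[np.random.Generator] = None
) -> GenomeSim:
    """Build the genome: layout, sequence, annotations and planted truth.

    Raises ``ValueError`` when the layout cannot host the requested elements.
    """
    cfg = config or SyntheticConfig()
    rng = rng or np.random.default_rng(cfg.seed)
    layout = GenomeLayout(cfg.chrom_sizes)
    comp_a, comp_b = _domains(layout, cfg.domain_size)
    a_by_chrom = comp_a.by_chrom()
    b_by_chrom = comp_b.by_chrom()
    rt_control = _latent_rt(cfg, layout)

    res = _Reservations()
    fw = cfg.flank_width

    # ---- genes (A domains) + expression --------------------------------
    genes = []
    for i in range(cfg.n_genes):
        w = int(rng.integers(*cfg.gene_length_range))
        iv = _place_in_domains(rng, layout, a_by_chrom, w, _Reservations(), margin=1000)
        if iv is None:
            raise ValueError("layout too small to place requested genes")
        genes.append(
            GenomicInterval(iv.chrom, iv.start, iv.end, f"gene_{i:04d}", 0.0, ".")
        )
    gene_set = IntervalSet(genes, layout=layout)
    expression = rng.lognormal(mean=2.0, sigma=1.0, size=len(gene_set))

    # ---- marked (specific-signal) domains on the 10 kb grid ------------
    # placement biased toward A/euchromatic domains (the mark is broadly
    # euchromatic), so compartment-level signal contrast is part of the truth
    block = 10_000
    a_bias = 0.8
    blocks = {c: np.zeros(layout[c] // block, dtype=bool) for c in layout}
    total_blocks = sum(v.size for v in blocks.values())
    target = int(round(cfg.marked_fraction * total_blocks))
    placed = 0
    tries = 0
    while placed < target:
        tries += 1
        if tries > 50 * target:
            raise ValueError("could not reach requested marked fraction")
        chrom = _pick_chrom(rng, layout)
        nb = int(rng.integers(
            cfg.marked_domain_range[0] // block, cfg.marked_domain_range[1] // block + 1
        ))
        nb = min(nb, target - placed)
        occ = blocks[chrom]
        if occ.size < nb:
            continue
        if rng.random() < a_bias:
            doms = [d for d in a_by_chrom.get(chrom, []) if len(d) // block >= nb]
            if not doms:
                continue
            dom = doms[rng.integers(len(doms))]
            lo, hi = dom.start // block, dom.end // block - nb
            s = int(rng.integers(lo, hi + 1))
        else:
            s = int(rng.integers(0, occ.size - nb + 1))
        if occ[s : s + nb].any():
            continue
        occ[s : s + nb] = True
        placed += nb
    marked_ivs = []
    for chrom, occ in blocks.items():
        edges = np.flatnonzero(np.diff(np.concatenate([[0], occ.view(np.int8), [0]])))
        for s, e in zip(edges[::2], edges[1::2]):
            marked_ivs.append(GenomicInterval(chrom, int(s) * block, int(e) * block))
    marked = IntervalSet(marked_ivs, layout=layout)
    marked_fraction = placed / total_blocks

    # specific ChIP rate on the coverage grid
    spec_data = {}
    for chrom in layout:
        n = layout.n_bins(chrom, cfg.coverage_bin)
        arr = np.zeros(n)
        for iv in (i for i in marked if i.chrom == chrom):
            arr[iv.start // cfg.coverage_bin : iv.end // cfg.coverage_bin] = (
                cfg.chip_specific_rate
            )
        spec_data[chrom] = arr
    specific_chip = CoverageTrack(layout, cfg.coverage_bin, spec_data, units="rate")

    # ---- nonspecific (promoter-like) peaks outside marked domains ------
    def _block_free(chrom, start, end):
        # one spare block on each side keeps promoter peaks from abutting
        # marked domains (they would merge into one called peak otherwise)
        occ = blocks[chrom]
        b0 = max(0, start // block - 1)
        b1 = (end - 1) // block + 2
        return b1 <= occ.size and not occ[b0:b1].any()

    peak_res = _Reservations()
    peaks = []
    order = rng.permutation(len(gene_set))
    for gi in order:
        if len(peaks) >= cfg.n_nonspecific_peaks:
            break
        g = gene_set[int(gi)]
        start = g.start // cfg.coverage_bin * cfg.coverage_bin
        end = start + cfg.nonspecific_peak_width
        if end > layout[g.chrom] or not _block_free(g.chrom, start, end):
            continue
        if peak_res.conflicts(g.chrom, start, end):
            continue
        peak_res.add(g.chrom, start, end)
        peaks.append(GenomicInterval(g.chrom, start, end, f"peak_{len(peaks):04d}"))
    while len(peaks) < cfg.n_nonspecific_peaks:
        chrom = _pick_chrom(rng, layout)
        start = int(rng.integers(0, layout[chrom] - cfg.nonspecific_peak_width))
        start = start // cfg.coverage_bin * cfg.coverage_bin
        end = start + cfg.nonspecific_peak_width
        if not _block_free(chrom, start, end) or peak_res.conflicts(chrom, start, end):
            continue
        peak_res.add(chrom, start, end)
        peaks.append(GenomicInterval(chrom, start, end, f"peak_{len(peaks):04d}"))
    nonspecific = IntervalSet(peaks, layout=layout)

    # ---- initiation zones ----------------------------------------------
    zone_res = _Reservations()   # zones keep >= 50 kb separation via padding
    pad = 50_000
    margin = 50_000
    pool_a = _SegmentPool([
        GenomicInterval(iv.chrom, iv.start + margin, iv.end - margin)
        for iv in comp_a if len(iv) > 2 * margin
    ])
    pool_b = _SegmentPool([
        GenomicInterval(iv.chrom, iv.start + margin, iv.end - margin)
        for iv in comp_b if len(iv) > 2 * margin
    ])

    def _place_zone(pool, width):
        chrom, start = pool.place(rng, width + 2 * pad, grid=cfg.coverage_bin)
        zone_res.add(chrom, start, start + width + 2 * pad)
        return GenomicInterval(chrom, start + pad, start + pad + width)

    # amplitude draws are clipped away from the detection threshold so that
    # every planted zone is a real plateau, not a borderline excursion
    def _zone_amp(size=None):
        draw = rng.lognormal(0.0, cfg.edu_zone_rate_sigma, size)
        return cfg.edu_zone_rate * np.clip(draw, 0.8, 3.0)

    const = []
    amps = _zone_amp(cfg.n_constitutive_zones)
    for i in range(cfg.n_constitutive_zones):
        w = int(rng.integers(*cfg.zone_width_range)) // cfg.coverage_bin * cfg.coverage_bin
        iv = _place_zone(pool_a, w)
        const.append(GenomicInterval(iv.chrom, iv.start, iv.end,
                                     f"zone|const_{i:03d}", float(amps[i])))
    const_set = IntervalSet(const, layout=layout)
    order = np.argsort([-iv.score for iv in const_set])
    hyper_names = frozenset(const_set[int(i)].name for i in order[: len(order) // 2])

    n_deact = max(2, cfg.n_constitutive_zones // 8)
    deact = []
    for i in range(n_deact):
        w = int(rng.integers(*cfg.zone_width_range)) // cfg.coverage_bin * cfg.coverage_bin
        amp = float(_zone_amp())
        iv = _place_zone(pool_a, w)
        deact.append(GenomicInterval(iv.chrom, iv.start, iv.end,
                                     f"zone|deact_{i:03d}", amp))
    deact_set = IntervalSet(deact, layout=layout)

    # de novo zones over LTR clusters in late (B) domains
    denovo = []
    cluster_ltrs = []
    for i in range(cfg.n_denovo_zones):
        w = int(rng.integers(*cfg.denovo_width_range)) // cfg.coverage_bin * cfg.coverage_bin
        iv = _place_zone(pool_b, w)
        denovo.append(GenomicInterval(iv.chrom, iv.start, iv.end,
                                      f"zone|denovo_{i:03d}"))
        span_lo = iv.start + 20_000
        span_hi = iv.end - 20_000
        k = cfg.ltrs_per_denovo_cluster
        centers = np.linspace(span_lo, span_hi, k).astype(int)
        for j, c in enumerate(centers):
            body = int(rng.integers(*cfg.ltr_length_range))
            s = int(c) - body // 2
            strand = "+" if rng.random() < 0.5 else "-"
            cluster_ltrs.append(GenomicInterval(
                iv.chrom, s, s + body, f"LTR|denovo_{i:03d}_{j}", 0.0, strand))
            res.add(iv.chrom, s - fw - 10, s + body + fw + 10)
    denovo_set = IntervalSet(denovo, layout=layout)

    # ---- TE catalog -----------------------------------------------------
    # solo activated LTRs in late bins away from zones (the KO anticipates
    # replication timing at all activated LTRs, not only de novo clusters)
    n_solo = max(0, 6 * cfg.n_denovo_zones)
    solo_ltrs = []
    late_positions = []
    for chrom, r in rt_control.items():
        late = np.flatnonzero(r <= -0.5 * cfg.rt_amplitude)
        for b in late:
            late_positions.append((chrom, int(b) * cfg.rt_bin + cfg.rt_bin // 2))
    rng.shuffle(late_positions)
    used_bins = set()
    for chrom, center in late_positions:
        if len(solo_ltrs) >= n_solo:
            break
        if zone_res.conflicts(chrom, center - 1000, center + 1000):
            continue
        key = (chrom, center // cfg.rt_bin)
        if key in used_bins:
            continue
        body = int(rng.integers(*cfg.ltr_length_range))
        s = center - body // 2
        if res.conflicts(chrom, s - fw - 10, s + body + fw + 10):
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        solo_ltrs.append(GenomicInterval(
            chrom, s, s + body, f"LTR|solo_{len(solo_ltrs):03d}", 0.0, strand))
        res.add(chrom, s - fw - 10, s + body + fw + 10)
        used_bins.add(key)

    background_ltrs = []
    for i in range(cfg.n_ltr):
        body = int(rng.integers(*cfg.ltr_length_range))
        doms = b_by_chrom if rng.random() < cfg.ltr_b_bias else a_by_chrom
        iv = _place_in_domains(rng, layout, doms, body + 2 * (fw + 10), res,
                               margin=1000)
        if iv is None:
            raise ValueError("layout too small to place requested LTRs")
        strand = "+" if rng.random() < 0.5 else "-"
        background_ltrs.append(GenomicInterval(
            iv.chrom, iv.start + fw + 10, iv.start + fw + 10 + body,
            f"LTR|bg_{i:04d}", 0.0, strand))

    sines = []
    for i in range(cfg.n_sine):
        body = int(rng.integers(*cfg.sine_length_range))
        iv = _place_in_domains(rng, layout, a_by_chrom, body, res, margin=1000)
        if iv is None:
            raise ValueError("layout too small to place requested SINEs")
        strand = "+" if rng.random() < 0.5 else "-"
        sines.append(GenomicInterval(iv.chrom, iv.start, iv.end,
                                     f"SINE|{i:04d}", 0.0, strand))

    activated = IntervalSet(cluster_ltrs + solo_ltrs, layout=layout)
    catalog = IntervalSet(cluster_ltrs + solo_ltrs + background_ltrs + sines,
                          layout=layout)

    # ---- KO timing program ---------------------------------------------
    rt_ko = {}
    act_by_chrom = activated.by_chrom()
    for chrom, r in rt_control.items():
        shifted = cfg.rt_flattening * r.copy()
        for iv in act_by_chrom.get(chrom, []):
            b0 = iv.start // cfg.rt_bin
            b1 = (iv.end - 1) // cfg.rt_bin + 1
            shifted[b0:b1] = cfg.rt_flattening * r[b0:b1] + cfg.rt_anticipation
        rt_ko[chrom] = np.clip(shifted, -1.0, 1.0)

    # ---- sequence -------------------------------------------------------
    sequence = {}
    for chrom in layout:
        seq = _random_base_segment(rng, layout[chrom], cfg.at_background)
        for iv in (i for i in catalog if i.chrom == chrom and i.name.startswith("LTR|")):
            s, e = iv.start, iv.end
            seq[s:e] = _random_base_segment(rng, e - s, cfg.at_ltr_body)
            seq[s - fw : s] = _random_base_segment(rng, fw, cfg.at_flank)
            seq[e : e + fw] = _random_base_segment(rng, fw, cfg.at_flank)
            tl = cfg.tract_length
            off = (fw - tl) // 2
            left_base, right_base = (_A, _T) if iv.strand == "+" else (_T, _A)
            seq[s - fw + off : s - fw + off + tl] = _tract(rng, tl, left_base)
            seq[e + off : e + off + tl] = _tract(rng, tl, right_base)
        sequence[chrom] = _BASES[seq].tobytes().decode("ascii")

    truth = SyntheticTruth(
        layout=layout,
        compartments_a=comp_a,
        compartments_b=comp_b,
        genes=gene_set,
        gene_expression=expression,
        te_catalog=catalog,
        activated_ltrs=activated,
        nonspecific_peaks=nonspecific,
        marked=marked,
        marked_fraction=marked_fraction,
        specific_chip=specific_chip,
        constitutive_zones=const_set,
        hyper_zone_names=hyper_names,
        denovo_zones=denovo_set,
        deactivated_zones=deact_set,
        rt_program={"control": rt_control, "ko": rt_ko},
        rt_bin=cfg.rt_bin,
    )
    return GenomeSim(layout=layout, sequence=sequence, truth=truth)


# ---------------------------------------------------------------------------
# signal simulators


def _nonspecific_rate(cfg: SyntheticConfig, truth: SyntheticTruth) -> Dict[str, np.ndarray]:
    rate = {c: np.zeros(truth.layout.n_bins(c, cfg.coverage_bin)) for c in truth.layout}
    for iv in truth.nonspecific_peaks:
        b0 = iv.start // cfg.coverage_bin
        b1 = -(-iv.end // cfg.coverage_bin)
        rate[iv.chrom][b0:b1] += cfg.nonspecific_peak_rate
    return rate


def simulate_chip(
    config: SyntheticConfig,
    truth: SyntheticTruth,
    rng: Optional[np.random.Generator] = None,
) -> ChipSim:
    """Control and KO ChIP replicates plus spike-in read counts.

    Control coverage ~ Poisson(lib * (base + specific + nonspecific)),
    KO coverage ~ Poisson(lib * (base + nonspecific)); the nonspecific
    component is identical in expectation across conditions. ``lib`` is a
    per-sample lognormal library-size factor; spike-in reads scale with it
    (plus small independent jitter), so spike-in RPM scaling undoes it.
    """
    rng = rng or np.random.default_rng(config.seed)
    nonspec = _nonspecific_rate(config, truth)
    base = config.chip_base_rate
    spec = truth.specific_chip.data

    n = config.n_chip_replicates
    libs = rng.lognormal(0.0, config.library_jitter_sd, size=2 * n)
    control, ko, spikein = [], [], {}
    for i in range(n):
        lib = libs[i]
        data = {
            c: rng.poisson(lib * (base + spec[c] + nonspec[c])).astype(float)
            for c in truth.layout
        }
        control.append(CoverageTrack(truth.layout, config.coverage_bin, data))
        spikein[f"control_rep{i + 1}"] = int(
            rng.poisson(config.spikein_depth * lib * rng.lognormal(0.0, 0.02))
        )
    for i in range(n):
        lib = libs[n + i]
        data = {
            c: rng.poisson(lib * (base + nonspec[c])).astype(float)
            for c in truth.layout
        }
        ko.append(CoverageTrack(truth.layout, config.coverage_bin, data))
        spikein[f"ko_rep{i + 1}"] = int(
            rng.poisson(config.spikein_depth * lib * rng.lognormal(0.0, 0.02))
        )
    return ChipSim(control=control, ko=ko, spikein=spikein)


def _edu_rate(cfg: SyntheticConfig, truth: SyntheticTruth, condition: str) -> Dict[str, np.ndarray]:
    if condition not in EDU_CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; use one of {EDU_CONDITIONS}")
    bs = cfg.coverage_bin
    rate = {
        c: np.full(truth.layout.n_bins(c, bs), cfg.edu_background)
        for c in truth.layout
    }
    factor = {"control": 1.0, "ko": cfg.hyperactivation_factor,
              "cmyc": cfg.cmyc_factor}[condition]
    for iv in truth.constitutive_zones:
        b0, b1 = iv.start // bs, iv.end // bs
        f = factor if iv.name in truth.hyper_zone_names else 1.0
        rate[iv.chrom][b0:b1] = f * (cfg.edu_background + iv.score)
    for iv in truth.deactivated_zones:
        b0, b1 = iv.start // bs, iv.end // bs
        amp = iv.score * (0.25 if condition == "ko" else 1.0)
        rate[iv.chrom][b0:b1] = cfg.edu_background + amp
    if condition == "ko":
        for iv in truth.denovo_zones:
            b0, b1 = iv.start // bs, iv.end // bs
            rate[iv.chrom][b0:b1] += cfg.edu_zone_rate
        for iv in truth.activated_ltrs:
            b0 = iv.start // bs
            b1 = (iv.end - 1) // bs + 1
            rate[iv.chrom][b0:b1] += cfg.edu_ltr_bump
    return rate


def simulate_eduhu(
    config: SyntheticConfig,
    truth: SyntheticTruth,
    condition: str,
    rng: Optional[np.random.Generator] = None,
) -> List[CoverageTrack]:
    """Replicate nascent-DNA (EdU-HU) coverage for one condition.

    Control: background plus plateaus over constitutive/deactivated zones.
    KO: the strongest half of constitutive zones is hyperactivated, de novo
    plateaus appear over activated-LTR clusters (with locally elevated signal
    at LTR bodies) and deactivated zones lose most of their amplitude.
    "cmyc" mimics a stronger hyperactivation without LTR de novo zones.
    """
    rng = rng or np.random.default_rng(config.seed)
    rate = _edu_rate(config, truth, condition)
    reps = []
    for _ in range(config.n_edu_replicates):
        lib = rng.lognormal(0.0, config.library_jitter_sd)
        data = {c: rng.poisson(lib * rate[c]).astype(float) for c in truth.layout}
        reps.append(CoverageTrack(truth.layout, config.coverage_bin, data))
    return reps


def simulate_repliseq(
    config: SyntheticConfig,
    truth: SyntheticTruth,
    condition: str,
    rng: Optional[np.random.Generator] = None,
) -> List[Tuple[CoverageTrack, CoverageTrack]]:
    """Early/late replicate counts per 50 kb bin for one condition.

    Per bin with latent timing value r, the total count is Poisson with the
    configured depth and splits Binomial(N, (1+r)/2) into early vs late, so
    the (e-l)/(e+l) timing index is unbiased for r.
    """
    if condition not in truth.rt_program:
        raise ValueError(f"unknown condition {condition!r}")
    rng = rng or np.random.default_rng(config.seed)
    program = truth.rt_program[condition]
    reps = []
    for _ in range(config.n_rt_replicates):
        early_d, late_d = {}, {}
        for chrom, r in program.items():
            total = rng.poisson(config.repliseq_depth, size=r.size)
            early = rng.binomial(total, (1.0 + r) / 2.0)
            early_d[chrom] = early.astype(float)
            late_d[chrom] = (total - early).astype(float)
        reps.append(
            (
                CoverageTrack(truth.layout, config.rt_bin, early_d),
                CoverageTrack(truth.layout, config.rt_bin, late_d),
            )
        )
    return reps


@dataclass
class SimulatedStudy:
    config: SyntheticConfig
    genome: GenomeSim
    chip: ChipSim
    eduhu: Dict[str, List[CoverageTrack]]
    repliseq: Dict[str, List[Tuple[CoverageTrack, CoverageTrack]]]

    @property
    def truth(self) -> SyntheticTruth:
        return self.genome.truth


def simulate_study(config: Optional[SyntheticConfig] = None) -> SimulatedStudy:
    """Run the full generator with independent, seed-derived streams per
    component (deterministic for a given config)."""
    cfg = config or SyntheticConfig()
    ss = np.random.SeedSequence(cfg.seed)
    keys = ("genome", "chip", "edu_control", "edu_ko", "edu_cmyc",
            "rt_control", "rt_ko")
    streams = dict(zip(keys, (np.random.default_rng(c) for c in ss.spawn(len(keys)))))
    genome = simulate_genome(cfg, streams["genome"])
    chip = simulate_chip(cfg, genome.truth, streams["chip"])
    eduhu = {
        cond: simulate_eduhu(cfg, genome.truth, cond, streams[f"edu_{cond}"])
        for cond in ("control", "ko", "cmyc")
    }
    repliseq = {
        cond: simulate_repliseq(cfg, genome.truth, cond, streams[f"rt_{cond}"])
        for cond in ("control", "ko")
    }
    return SimulatedStudy(cfg, genome, chip, eduhu, repliseq)
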