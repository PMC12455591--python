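"""End-to-end workflows over a simulated or on-disk dataset.

``run_pipeline`` wires the stages together the way the study's analyses run:
``simulate`` writes a complete synthetic dataset (genome FASTA, annotation
BEDs, ChIP/EdU coverage bedGraphs, REPLI-seq early/late tracks, truth JSON);
``chip``/``zones``/``rt``/``seqfeat`` consume those files and write their
results; ``all`` runs every analysis stage. Outputs are deterministic given
the config and seed (no timestamps), and a JSON manifest records seeds,
thresholds and input checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__
from . import chip as chipmod
from . import io as gio
from . import seqfeat, timing, zones as zonemod
from .config import RunConfig, SyntheticConfig, write_manifest
from .genomic import CoverageTrack, GenomicInterval, IntervalSet, central_window
from .simulate import simulate_study

logger = logging.getLogger(__name__)

WORKFLOWS = ("simulate", "chip", "zones", "rt", "seqfeat", "all")

EDU_SAMPLES = [("control", 1), ("control", 2), ("ko", 1), ("ko", 2)]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    workflow: str,
    outdir,
    data_dir=None,
    syn_config: Optional[SyntheticConfig] = None,
    run_config: Optional[RunConfig] = None,
) -> Path:
    """Run one workflow; returns the output directory.

    ``simulate`` needs no ``data_dir``; the analysis workflows read the
    files a previous ``simulate`` run (or equivalently formatted real data)
    left in ``data_dir``. Raises ``FileNotFoundError`` before any
    computation when a required input is missing.
    """
    if workflow not in WORKFLOWS:
        raise ValueError(f"unknown workflow {workflow!r}; choose from {WORKFLOWS}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scfg = syn_config or SyntheticConfig()
    rcfg = run_config or RunConfig()

    if workflow == "simulate":
        inputs = {}
        _simulate(outdir, scfg)
    else:
        if data_dir is None:
            raise FileNotFoundError("analysis workflows require data_dir")
        data_dir = Path(data_dir)
        required = ["chrom.sizes", "te_catalog.bed"]
        if workflow in ("chip", "all"):
            required += ["chip/spikein_counts.tsv"]
        if workflow in ("seqfeat", "all"):
            required += ["genome.fa"]
        missing = [r for r in required if not (data_dir / r).exists()]
        if missing:
            raise FileNotFoundError(f"missing inputs in {data_dir}: {missing}")
        inputs = {str(p.relative_to(data_dir)): _sha256(p)
                  for p in sorted(data_dir.rglob("*")) if p.is_file()}
        layout = gio.read_chrom_sizes(data_dir / "chrom.sizes")
        if workflow in ("chip", "all"):
            _analyze_chip(data_dir, outdir, layout, rcfg)
        if workflow in ("zones", "all"):
            _analyze_zones(data_dir, outdir, layout, rcfg)
        if workflow in ("rt", "all"):
            _analyze_rt(data_dir, outdir, layout, rcfg)
        if workflow in ("seqfeat", "all"):
            _analyze_seqfeat(data_dir, outdir, rcfg)

    write_manifest(
        outdir / "manifest.json",
        version=__version__,
        workflow=workflow,
        synthetic_config=scfg.to_dict(),
        run_config=rcfg.to_dict(),
        overridden=rcfg.diff(),
        inputs=inputs,
    )
    return outdir


# ---------------------------------------------------------------------------


def _simulate(outdir: Path, cfg: SyntheticConfig) -> None:
    study = simulate_study(cfg)
    truth = study.truth
    layout = truth.layout
    gio.write_chrom_sizes(layout, outdir / "chrom.sizes")
    gio.write_fasta(study.genome.sequence, outdir / "genome.fa")
    gio.write_bed(truth.te_catalog, outdir / "te_catalog.bed")
    gio.write_bed(truth.genes, outdir / "genes.bed")
    pd.DataFrame(
        {
            "gene": [g.name for g in truth.genes],
            "expression": truth.gene_expression,
        }
    ).to_csv(outdir / "gene_expression.tsv", sep="\t", index=False,
             float_format="%.6g")
    gio.write_bed(truth.compartments_a, outdir / "compartments_A.bed", columns=3)
    gio.write_bed(truth.compartments_b, outdir / "compartments_B.bed", columns=3)

    chipdir = outdir / "chip"
    chipdir.mkdir(exist_ok=True)
    for name, track in study.chip.samples().items():
        gio.write_bedgraph(track, chipdir / f"{name}.bedgraph")
    pd.DataFrame(
        sorted(study.chip.spikein.items()), columns=["sample", "spikein_reads"]
    ).to_csv(chipdir / "spikein_counts.tsv", sep="\t", index=False)

    edudir = outdir / "edu"
    edudir.mkdir(exist_ok=True)
    for cond, reps in study.eduhu.items():
        for i, track in enumerate(reps, 1):
            gio.write_bedgraph(track, edudir / f"{cond}_rep{i}.bedgraph")

    rtdir = outdir / "repliseq"
    rtdir.mkdir(exist_ok=True)
    for cond, reps in study.repliseq.items():
        for i, (early, late) in enumerate(reps, 1):
            gio.write_bedgraph(early, rtdir / f"{cond}_rep{i}_early.bedgraph")
            gio.write_bedgraph(late, rtdir / f"{cond}_rep{i}_late.bedgraph")

    truth.to_json(outdir / "truth.json")


# ---------------------------------------------------------------------------


def _read_chip(data_dir: Path, layout, bin_size: int) -> Dict[str, CoverageTrack]:
    out = {}
    for p in sorted((data_dir / "chip").glob("*.bedgraph")):
        out[p.stem] = gio.read_bedgraph(p, bin_size, layout)
    if not out:
        raise FileNotFoundError(f"no ChIP bedGraph files under {data_dir}/chip")
    return out


def _coverage_bin(data_dir: Path, layout) -> int:
    # infer the coverage grid from the smallest record in one bedGraph
    p = sorted((data_dir / "chip").glob("*.bedgraph"))
    probe = p[0] if p else sorted((data_dir / "edu").glob("*.bedgraph"))[0]
    best = None
    with open(probe) as fh:
        for _ in range(2000):
            line = fh.readline()
            if not line:
                break
            parts = line.split("\t")
            w = int(parts[2]) - int(parts[1])
            best = w if best is None else min(best, w)
    return best or 1000


def _analyze_chip(data_dir: Path, outdir: Path, layout, rcfg: RunConfig) -> None:
    bin_size = _coverage_bin(data_dir, layout)
    tracks = _read_chip(data_dir, layout, bin_size)
    ctrl_names = sorted(n for n in tracks if n.startswith("control"))
    ko_names = sorted(n for n in tracks if n.startswith("ko"))

    corrected = chipmod.knockout_correct(
        [tracks[n] for n in ctrl_names],
        [tracks[n] for n in ko_names],
        scaling="common-peak",
        top_n=rcfg.top_n_common_peaks,
        peak_z=rcfg.peak_z,
    )
    gio.write_bedgraph(corrected.track, outdir / "chip_corrected.bedgraph")

    pos = chipmod.genome_fraction_marked(corrected.track, rcfg.positivity_bin)
    comp_a = gio.read_bed(data_dir / "compartments_A.bed", layout)
    comp_b = gio.read_bed(data_dir / "compartments_B.bed", layout)
    a_vals, b_vals, comp_p = chipmod.compartment_signal(
        corrected.track, comp_a, comp_b, rcfg.compartment_bin
    )
    genes = gio.read_bed(data_dir / "genes.bed", layout)
    expr_df = pd.read_csv(data_dir / "gene_expression.tsv", sep="\t")
    expr = expr_df.set_index("gene").loc[[g.name for g in genes], "expression"]
    quartiles, quart_p = chipmod.gene_quartile_signal(
        corrected.track, genes, expr.to_numpy()
    )
    summary = {
        "scaling_method": corrected.scaling_method,
        "positivity_threshold_log1p": round(pos.threshold, 6),
        "fraction_marked_percent": round(pos.fraction_marked, 4),
        "compartment_A_median": round(float(np.median(a_vals)), 6),
        "compartment_B_median": round(float(np.median(b_vals)), 6),
        "compartment_ranksum_p": float(comp_p),
        "quartile_medians_low_to_high": [
            round(float(np.median(q)), 6) for q in quartiles
        ],
        "quartile_kruskal_p": float(quart_p),
    }
    with open(outdir / "chip_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _sum_tracks(tracks: List[CoverageTrack]) -> CoverageTrack:
    data = {
        c: np.sum([t.data[c] for t in tracks], axis=0) for c in tracks[0].layout
    }
    return CoverageTrack(tracks[0].layout, tracks[0].bin_size, data,
                         units=tracks[0].units)


def _read_edu(data_dir: Path, layout, bin_size: int) -> Dict[str, CoverageTrack]:
    out = {}
    for p in sorted((data_dir / "edu").glob("*.bedgraph")):
        out[p.stem] = gio.read_bedgraph(p, bin_size, layout)
    if not out:
        raise FileNotFoundError(f"no EdU bedGraph files under {data_dir}/edu")
    return out


def _analyze_zones(data_dir: Path, outdir: Path, layout, rcfg: RunConfig) -> None:
    bin_size = _coverage_bin(data_dir, layout)
    edu = _read_edu(data_dir, layout, bin_size)
    samples = {n: t for n, t in edu.items()
               if n.startswith(("control", "ko"))}
    peak_sets = [
        zonemod.threshold_call_peaks(t, rcfg.peak_z, rcfg.peak_min_run)
        for _, t in sorted(samples.items())
    ]
    zone_set = zonemod.call_zones(peak_sets, rcfg.merge_gap, rcfg.min_size)
    gio.write_bed(zone_set, outdir / "zones.bed", columns=6)

    counts = zonemod.count_reads_in_intervals(zone_set, samples)
    design = {n: ("ko" if n.startswith("ko") else "control") for n in samples}
    lib = {n: float(samples[n].values().sum()) for n in samples}
    stats_df = zonemod.zone_statistics(zone_set, counts, design,
                                       lib_sizes=lib)
    classified = zonemod.classify_zones(
        stats_df, rcfg.conc_min, rcfg.lfc_min, rcfg.zone_fdr_max
    )
    classified.to_csv(outdir / "zones_classified.tsv", sep="\t", index=False,
                      float_format="%.6g")

    by_class = {
        cls: zone_set.subset((classified["class"] == cls).to_list())
        for cls in ("constitutive", "activated", "deactivated")
    }
    te = gio.read_bed(data_dir / "te_catalog.bed", layout)
    ltrs = IntervalSet(iv for iv in te if iv.name.startswith("LTR|"))
    sines = IntervalSet(iv for iv in te if iv.name.startswith("SINE|"))
    genes = gio.read_bed(data_dir / "genes.bed", layout)
    abundance = zonemod.zone_gene_abundance(by_class, genes, layout,
                                            rcfg.central_width)

    background = by_class["constitutive"].union(by_class["deactivated"])
    bg_windows = IntervalSet(
        central_window(iv, rcfg.central_width, layout) for iv in background
    )
    enrich = {}
    if len(by_class["activated"]):
        q_windows = IntervalSet(
            central_window(iv, rcfg.central_width, layout)
            for iv in by_class["activated"]
        )
        for fname, feats in (("LTR", ltrs), ("SINE", sines)):
            res = zonemod.permutation_enrichment(
                q_windows, feats, bg_windows,
                n=rcfg.n_permutations, seed=rcfg.seed,
            )
            enrich[fname] = {
                "observed": res.observed, "null_mean": round(res.null_mean, 4),
                "null_sd": round(res.null_sd, 4),
                "z": None if np.isnan(res.z) else round(res.z, 4),
                "p_value": res.p_value, "n_permutations": res.n_permutations,
                "seed": res.seed,
            }

    # hyperactivation of the strongest half of constitutive zones
    const = classified[classified["class"] == "constitutive"]
    top = const.nlargest(max(1, len(const) // 2), "conc_control")
    mean_lib = np.mean(list(lib.values()))
    ctrl_cols = [n for n in samples if n.startswith("control")]
    ko_cols = [n for n in samples if n.startswith("ko")]
    ctrl_norm = sum(counts.loc[top.index, n] * (mean_lib / lib[n]) for n in ctrl_cols) / len(ctrl_cols)
    ko_norm = sum(counts.loc[top.index, n] * (mean_lib / lib[n]) for n in ko_cols) / len(ko_cols)
    hyper_stat, hyper_p = zonemod.hyperactivation_test(ctrl_norm, ko_norm)

    summary = {
        "n_zones": len(zone_set),
        "mean_zone_size_bp": round(float(np.mean([len(z) for z in zone_set])), 1),
        "n_activated": int((classified["class"] == "activated").sum()),
        "n_deactivated": int((classified["class"] == "deactivated").sum()),
        "n_constitutive": int((classified["class"] == "constitutive").sum()),
        "gene_abundance_central_window": {
            k: (None if np.isnan(v) else round(v, 4)) for k, v in abundance.items()
        },
        "enrichment": enrich,
        "hyperactivation_p": hyper_p,
    }
    with open(outdir / "zones_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _read_repliseq(data_dir: Path, layout, rt_bin: int):
    reps: Dict[str, List] = {"control": [], "ko": []}
    for cond in reps:
        i = 1
        while (data_dir / "repliseq" / f"{cond}_rep{i}_early.bedgraph").exists():
            early = gio.read_bedgraph(
                data_dir / "repliseq" / f"{cond}_rep{i}_early.bedgraph", rt_bin, layout
            )
            late = gio.read_bedgraph(
                data_dir / "repliseq" / f"{cond}_rep{i}_late.bedgraph", rt_bin, layout
            )
            reps[cond].append((early, late))
            i += 1
        if not reps[cond]:
            raise FileNotFoundError(f"no REPLI-seq files for condition {cond}")
    return reps


def _analyze_rt(data_dir: Path, outdir: Path, layout, rcfg: RunConfig) -> None:
    reps = _read_repliseq(data_dir, layout, rcfg.rt_bin)
    rtis = {
        cond: [timing.rti_track(e, l) for e, l in pairs]
        for cond, pairs in reps.items()
    }
    bins = timing.differential_rt(
        rtis["control"], rtis["ko"], rcfg.drti_min, rcfg.rt_fdr_max
    )
    bins.to_csv(outdir / "rt_bins.tsv", sep="\t", index=False,
                float_format="%.6g")
    regions = timing.merge_rt_regions(bins)
    control_mean = _mean_tracks(rtis["control"])
    for r in regions:
        r.transition = timing.transition_classify(r, control_mean)
    with open(outdir / "rt_regions.bed", "w") as fh:
        for r in regions:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.direction}\t"
                f"{r.mean_drti:.6g}\t.\t{int(r.transition)}\n"
            )

    # browsing track: log2 early/late of the merged control replicates
    e_sum = _sum_tracks([e for e, _ in reps["control"]])
    l_sum = _sum_tracks([l for _, l in reps["control"]])
    gio.write_bedgraph(
        timing.rt_log2_track(e_sum, l_sum, rcfg.pseudocount),
        outdir / "rt_log2_control.bedgraph",
    )

    te = gio.read_bed(data_dir / "te_catalog.bed", layout)
    ltrs = IntervalSet(iv for iv in te if iv.name.startswith("LTR|"))
    elem = {}
    for cond in ("control", "ko"):
        e, l = reps[cond][0]
        for mode in ("regional", "local"):
            vals = timing.element_rt(ltrs, e, l, mode=mode,
                                     window=rcfg.rt_bin,
                                     pseudocount=rcfg.pseudocount)
            elem[f"ltr_{mode}_{cond}_median"] = round(
                float(np.nanmedian(vals)), 6
            )

    comparison = timing.global_rt_compare(
        _mean_tracks(rtis["control"]), _mean_tracks(rtis["ko"])
    )
    n_anticipated = sum(r.direction == "anticipated" for r in regions)

    anticipated = IntervalSet(
        GenomicInterval(r.chrom, r.start, r.end) for r in regions
        if r.direction == "anticipated"
    )
    enrich = None
    if len(anticipated):
        res = zonemod.permutation_enrichment(
            anticipated, ltrs, mode="genome", layout=layout,
            n=rcfg.n_permutations, seed=rcfg.seed,
        )
        enrich = {"observed": res.observed, "null_mean": round(res.null_mean, 4),
                  "null_sd": round(res.null_sd, 4),
                  "z": None if np.isnan(res.z) else round(res.z, 4),
                  "p_value": res.p_value,
                  "n_permutations": res.n_permutations, "seed": res.seed}

    summary = {
        "n_differential_bins": int(bins["flagged"].sum()),
        "n_regions": len(regions),
        "n_anticipated": int(n_anticipated),
        "n_delayed": int(len(regions) - n_anticipated),
        "fraction_anticipated": round(n_anticipated / len(regions), 4)
        if regions else None,
        "fraction_at_transition": round(
            float(np.mean([r.transition for r in regions])), 4
        ) if regions else None,
        "flattening_slope": round(comparison.slope, 6),
        "early_mean_control": round(comparison.early_mean_control, 6),
        "early_mean_ko": round(comparison.early_mean_ko, 6),
        "late_mean_control": round(comparison.late_mean_control, 6),
        "late_mean_ko": round(comparison.late_mean_ko, 6),
        "ltr_enrichment": enrich,
        **elem,
    }
    with open(outdir / "rt_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _mean_tracks(tracks: List[CoverageTrack]) -> CoverageTrack:
    data = {
        c: np.nanmean([t.data[c] for t in tracks], axis=0)
        for c in tracks[0].layout
    }
    return CoverageTrack(tracks[0].layout, tracks[0].bin_size, data,
                         units=tracks[0].units)


def _analyze_seqfeat(data_dir: Path, outdir: Path, rcfg: RunConfig) -> None:
    seqs = gio.read_fasta(data_dir / "genome.fa")
    content = seqfeat.nucleotide_content(seqs, rcfg.content_bin)
    for base in ("A", "C", "G", "T", "AT"):
        gio.write_bedgraph(content[base], outdir / f"content_{base}.bedgraph")
    masks = {}
    for base in ("A", "T"):
        masks[base] = seqfeat.poly_tract_mask(
            seqs, base, rcfg.tract_min_len, rcfg.tract_min_frac
        )
        gio.write_bedgraph(masks[base], outdir / f"poly_d{base}_mask.bedgraph")

    layout = gio.read_chrom_sizes(data_dir / "chrom.sizes")
    te = gio.read_bed(data_dir / "te_catalog.bed", layout)
    ltrs = IntervalSet(iv for iv in te if iv.name.startswith("LTR|"))
    if len(ltrs):
        _, at_mean, _ = seqfeat.stranded_profile(
            content["AT"], ltrs, 500, 500, body_cols=50
        )
        # per-base masks aggregated to the content grid for joint display
        maskA = masks["A"].rebin(rcfg.content_bin, "max")
        maskT = masks["T"].rebin(rcfg.content_bin, "max")
        _, pa_mean, _ = seqfeat.stranded_profile(maskA, ltrs, 500, 500, 50)
        _, pt_mean, _ = seqfeat.stranded_profile(maskT, ltrs, 500, 500, 50)
        prof = pd.DataFrame({
            "column": np.arange(at_mean.size),
            "at_percent": at_mean,
            "polyA_mask": pa_mean,
            "polyT_mask": pt_mean,
        })
        prof.to_csv(outdir / "ltr_profiles.tsv", sep="\t", index=False,
                    float_format="%.6g")
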