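"""Run configuration: every analysis threshold with its published default.

The thresholds live in one flat dataclass so a pipeline run can record them in
its manifest and a config file can override any of them individually.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class RunConfig:
    """Analysis thresholds (defaults as used throughout the package).

    Zone calling: peaks from any sample are combined, merged within
    ``merge_gap`` and kept at ``min_size``. Differential zones require a
    concentration of ``conc_min`` in at least one condition, ``|log2FC| >=
    lfc_min`` and ``FDR <= zone_fdr_max``. Differential replication timing
    requires ``|dRTI| > drti_min`` and ``FDR < rt_fdr_max``. Poly(dA)/poly(dT)
    tracts are runs of >= ``tract_min_len`` bp at >= ``tract_min_frac`` purity.
    """

    merge_gap: int = 10_000          # bp, zone merging
    min_size: int = 20_000           # bp, minimum zone size
    conc_min: float = 7.0            # log2 normalized counts, differential gate
    lfc_min: float = 0.7             # |log2FC| gate
    zone_fdr_max: float = 1e-10      # FDR gate for differential zones
    drti_min: float = 0.2            # |delta RTI| gate
    rt_fdr_max: float = 0.01         # FDR gate for differential RT bins
    n_permutations: int = 5000       # permutation test draws
    tract_min_len: int = 20          # bp
    tract_min_frac: float = 0.75
    content_bin: int = 5             # bp, nucleotide-content bins
    positivity_bin: int = 10_000     # bp, genome-fraction histogram bins
    compartment_bin: int = 50_000    # bp, A/B compartment assignment
    rt_bin: int = 50_000             # bp, REPLI-seq grid
    central_width: int = 50_000      # bp, central window for abundance/enrichment
    peak_min_run: int = 5_000        # bp, threshold peak caller minimum run
    peak_z: float = 3.0              # robust z cutoff for the threshold caller
    top_n_common_peaks: int = 10_000
    pseudocount: float = 1.0         # for log2 ratios
    seed: int = 0

    def override(self, **kwargs) -> "RunConfig":
        unknown = set(kwargs) - {f.name for f in dataclasses.fields(self)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load overrides from a flat TOML key/value file."""
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        return cls().override(**data)

    def diff(self) -> dict:
        """Keys that differ from the defaults (for the run manifest)."""
        base = dataclasses.asdict(RunConfig())
        mine = dataclasses.asdict(self)
        return {k: v for k, v in mine.items() if base[k] != v}


@dataclass
class SyntheticConfig:
    """Parameters of the planted-truth simulator (see docs/methods.md).

    The defaults describe a two-chromosome 2 x 20 Mb miniature genome with
    alternating 2 Mb early(A)/late(B) replication domains, H4K16ac-like
    specific signal over 40% of the genome, promoter-like nonspecific ChIP
    peaks shared by control and KO, EdU-HU initiation zones (constitutive plus
    KO-only de novo zones over LTR clusters in late domains), and a latent RT
    program that the KO flattens and locally anticipates at activated LTRs.
    """

    chrom_sizes: dict = field(
        default_factory=lambda: {"chr1": 20_000_000, "chr2": 20_000_000}
    )
    seed: int = 1
    coverage_bin: int = 1_000        # bp, ChIP/EdU coverage grid
    rt_bin: int = 50_000             # bp, REPLI-seq grid
    domain_size: int = 2_000_000     # bp, alternating A/B (early/late) domains

    # initiation zones
    n_constitutive_zones: int = 32
    zone_width_range: tuple = (120_000, 300_000)   # bp
    hyperactivation_factor: float = 1.3            # KO, strongest half of zones
    cmyc_factor: float = 1.6                       # cMYC-like condition
    n_denovo_zones: int = 8
    denovo_width_range: tuple = (80_000, 160_000)  # bp
    ltrs_per_denovo_cluster: int = 4

    # TE catalog
    n_ltr: int = 300
    ltr_length_range: tuple = (100, 1_000)         # bp
    ltr_b_bias: float = 0.8                        # P(LTR placed in B domain)
    n_sine: int = 300
    sine_length_range: tuple = (150, 400)          # bp

    # genes / expression
    n_genes: int = 400
    gene_length_range: tuple = (2_000, 20_000)     # bp

    # ChIP model
    marked_fraction: float = 0.40    # genome fraction carrying specific signal
    marked_domain_range: tuple = (100_000, 500_000)
    chip_base_rate: float = 2.0      # reads per coverage bin
    chip_specific_rate: float = 20.0
    n_nonspecific_peaks: int = 200
    nonspecific_peak_width: int = 2_000            # bp
    nonspecific_peak_rate: float = 120.0           # reads per bin at peak
    n_chip_replicates: int = 2
    library_jitter_sd: float = 0.1   # lognormal sigma of library size
    spikein_depth: int = 1_000_000   # expected spike-in reads per sample

    # EdU-HU model
    edu_background: float = 5.0      # reads per coverage bin
    edu_zone_rate: float = 30.0      # median plateau amplitude over background
    edu_zone_rate_sigma: float = 0.4 # lognormal spread of zone amplitudes
    edu_ltr_bump: float = 15.0       # extra rate at activated LTR bins
    n_edu_replicates: int = 2

    # REPLI-seq model
    rt_amplitude: float = 0.45       # |latent RTI| at domain centers
    repliseq_depth: int = 20_000     # mean reads (early+late) per 50 kb bin
    rt_flattening: float = 0.7       # KO latent program multiplier
    rt_anticipation: float = 0.4     # KO shift at bins with activated LTRs
    n_rt_replicates: int = 2

    # sequence model
    at_background: float = 0.50
    at_ltr_body: float = 0.40
    at_flank: float = 0.70
    flank_width: int = 200           # bp
    tract_length: int = 24           # bp, planted poly(dA)/(dT) tracts

    def __post_init__(self):
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        for name in (
            "n_constitutive_zones", "n_denovo_zones", "n_ltr", "n_sine",
            "n_genes", "n_nonspecific_peaks", "n_chip_replicates",
            "n_edu_replicates", "n_rt_replicates", "repliseq_depth",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("hyperactivation_factor", "cmyc_factor", "rt_flattening"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("ltr_b_bias", "marked_fraction", "at_background",
                     "at_ltr_body", "at_flank"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")

    def override(self, **kwargs) -> "SyntheticConfig":
        unknown = set(kwargs) - {f.name for f in dataclasses.fields(self)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return dataclasses.replace(self, **kwargs)

    def scaled_to(self, chrom_mb: int, **overrides) -> "SyntheticConfig":
        """A config for two ``chrom_mb`` Mb chromosomes with element counts
        scaled proportionally to genome length (rates and thresholds
        unchanged), for quick runs on a smaller coordinate space."""
        f = (2 * chrom_mb * 10**6) / sum(self.chrom_sizes.values())
        scaled = dict(
            chrom_sizes={"chr1": chrom_mb * 10**6, "chr2": chrom_mb * 10**6},
            n_constitutive_zones=max(4, round(self.n_constitutive_zones * f)),
            n_denovo_zones=max(2, round(self.n_denovo_zones * f)),
            n_ltr=max(20, round(self.n_ltr * f)),
            n_sine=max(20, round(self.n_sine * f)),
            n_genes=max(30, round(self.n_genes * f)),
            n_nonspecific_peaks=max(20, round(self.n_nonspecific_peaks * f)),
        )
        scaled.update(overrides)
        return self.override(**scaled)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def write_manifest(path, **sections) -> Path:
    """Write a machine-readable run manifest (JSON)."""
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(sections, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return path
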