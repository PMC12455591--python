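"""Generate a planted-truth synthetic study and look at what was planted.

The generator builds a miniature genome with alternating early/late
replication domains, an H4K16ac-like mark over ~40% of the genome,
knockout-shared nonspecific ChIP peaks, EdU-HU initiation zones (including
KO-only de novo zones over LTR clusters) and early/late REPLI-seq counts
from a latent timing program the KO flattens and locally anticipates.
"""

from repliq.config import SyntheticConfig
from repliq.simulate import simulate_study

# a 2 x 5 Mb genome with proportionally scaled element counts runs in seconds
config = SyntheticConfig(seed=1).scaled_to(5)
study = simulate_study(config)
truth = study.truth

print(f"genome: {dict(truth.layout.items())}")
print(f"planted marked fraction: {truth.marked_fraction:.3f} of the genome")
print(f"constitutive initiation zones: {len(truth.constitutive_zones)}"
      f" (strongest half hyperactivated in KO: {len(truth.hyper_zone_names)})")
print(f"KO-only de novo zones: {len(truth.denovo_zones)}"
      f" over {len(truth.activated_ltrs)} activated LTRs")
print(f"TE catalog: {len(truth.ltrs())} LTRs, {len(truth.sines())} SINEs")
print(f"ChIP samples: {sorted(study.chip.samples())}")
print(f"spike-in reads: {study.chip.spikein}")
# Every number above is ground truth the analysis stages must recover
# without seeing it; tests/ and scripts/acceptance.py score that recovery.
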