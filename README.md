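# repliq

Quantitative analysis of how a chromatin mark controls **DNA replication
timing**: knockout-corrected ChIP signal, replication initiation-zone calling
from nascent DNA, replication-timing-index (RTI) analysis, LTR sequence-
feature scanning and genomic permutation enrichment — packaged with a
planted-truth simulator so every stage can be validated end to end.

## Who this is for

Analysts working with ChIP-seq of broad histone marks (e.g. H4K16ac), EdU
/hydroxyurea nascent-DNA sequencing of replication initiation, and early/late
two-fraction REPLI-seq. The library implements the complete analysis chain
for the question *"does losing the mark re-wire where and when replication
starts?"* and, because public antibodies for such marks can carry substantial
nonspecific signal, treats a knockout (KO) cell line as the background
control for quantitative correction.

## The core methods

**Knockout-background ChIP correction.** Control and KO libraries are put on
a common scale either by spike-in reads-per-million (`factor = 10^6 /
spikein_reads`) or by equalizing read totals over the top shared peaks
(peaks detected in *both* samples; `factor_i = mean_j(T_j) / T_i`), then the
KO track is subtracted per bin with negatives clipped to zero. The fraction
of the genome carrying the mark is read off a bimodal histogram of 10 kb-bin
signal: the positivity threshold is the lowest-frequency bin between the two
modes.

**Initiation zones.** Peaks called in any nascent-DNA sample are combined,
merged within 10 kb and kept at ≥ 20 kb. Per zone, a concentration
`log2(mean normalized count + 1)` is computed per condition; zones are
*activated*/*deactivated* when concentration ≥ 7 in at least one condition,
|log2FC| ≥ 0.7 and FDR ≤ 1e−10 (exact conditional test of the Poisson rate
ratio on pooled counts, Benjamini–Hochberg over zones). Feature enrichment at
a zone class is assessed by a permutation test (`ntimes = 5000`) that redraws
zone-sized regions from a background set or from the genome.

**Replication timing.** Each 50 kb bin gets an RTI per replicate,

    RTI = (e − l) / (e + l)  ∈ [−1 (late), +1 (early)],

on depth-normalized early/late counts (no quantile normalization, so global
differences survive). Differential bins require |ΔRTI| > 0.2 and FDR < 0.01
from a per-bin t-test across replicates; adjacent same-direction bins merge
into *anticipated*/*delayed* regions, which are checked for monotone RTI
across their flanks (early/late transition areas). Genome-wide flattening is
summarized by the slope of a total-least-squares line through the origin fit
to (control, KO) RTI pairs — slope < 1 means the KO program is compressed
toward the middle line.

**Sequence features.** Per-5 bp nucleotide-content tracks and 0/100
poly(dA)/poly(dT) tract masks (target positions inside any ≥ 20 bp window at
≥ 75% of one nucleotide), profiled across LTR bodies with strand-aware
orientation — the antiparallel dA/dT flanks that characterize firing
replication origins.

**The simulator** (`repliq.simulate`) generates a miniature genome
(default 2 × 20 Mb) with all of the above planted as ground truth: marked
domains biased to euchromatic (A) compartments, shared promoter-like
nonspecific peaks, constitutive / hyperactivated / KO-only de novo zones over
LTR clusters, a sinusoidal latent timing program flattened (×0.7) and locally
anticipated (+0.4) in the KO, and sequence with AT-depleted LTR bodies
flanked by AT-rich regions carrying planted tracts.

## Worked example

`examples/` holds one short script per capability. Running
`python examples/02_chip_correction.py` (a 2 × 5 Mb simulated study) prints:

```
corrected vs true specific signal: Pearson r = 0.974
mean corrected signal left at nonspecific peaks: 9.55 (arbitrary coverage units; ~0 means the background was erased)
fraction of genome marked: 40.1% (planted: 40.0%)
signal in A vs B compartments: medians 26.9 vs 1.3, rank-sum p = 1.57e-07
```

i.e. the KO subtraction reconstructs the true specific signal (r = 0.97),
leaves ~3% of the control level at the shared nonspecific peaks, recovers the
planted 40% marked fraction from the bimodal histogram, and shows the
expected euchromatin bias. `examples/03_initiation_zones.py` continues:

```
called 12 zones, mean size 183 kb (12 planted)
{'constitutive': 8, 'activated': 2, 'deactivated': 2} <- de novo zones appear only in KO, hence 'activated'
LTR overlap at activated zones: observed 6 vs null 0.0, p = 2.0e-04 (activated zones sit on LTR clusters)
planted de novo zones recovered as activated: 100%
```

and `examples/04_replication_timing.py`:

```
differential bins: 18 of 200
10 regions: 10 anticipated, 0 delayed; 90% at E/L transitions
flattening slope (KO vs control RTI): 0.598 (< 1: late regions earlier, early regions later)
LTRs in anticipated regions: observed 35 vs random 8.8, p = 2.0e-04
```

## Command line

A thin CLI wraps the same workflows:

```bash
repliq run simulate --outdir sim --seed 1 --chrom-mb 5   # synthetic dataset
repliq run all --data-dir sim --outdir results --seed 1  # every analysis stage
```

`run all` writes the corrected ChIP bedGraph and summary, classified zones
(BED/TSV + enrichment JSON), RTI tables, differential-RT regions with
transition flags, log2 early/late tracks, nucleotide-content and tract-mask
bedGraphs, and a manifest recording seeds, thresholds and input checksums.
Outputs are byte-identical across reruns with the same seed.

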