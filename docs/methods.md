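# Methods

This note documents the models behind each analysis stage, the simulator
that generates the validation data, the numerical choices that are not
obvious from the code, and the limits of what the synthetic validation
shows.

## Coordinate and data model

All intervals are 0-based half-open (BED convention). Binned signal lives in
`CoverageTrack`: one value per fixed-size bin per chromosome, last bin
truncated at the chromosome end, with a units tag; negative values are only
legal for signed units (`log-ratio`, `difference`, `rti`). bedGraph is the
on-disk form (a bigWig stand-in): the writer run-length-merges consecutive
equal-valued bins, the reader expands records against the bin grid, so the
round trip is exact. Off-grid records can be re-binned by length-weighted
mean, but only on request — silent re-binning hides mismatched inputs.

Interval primitives (merging within a gap, half-open overlap counting,
central windows, genome tiling, metaprofiles) are implemented directly and
are each checked against brute-force enumerations in the test suite.
`merge_within` uses inclusive gap semantics (gap ≤ `max_gap` merges),
matching the common `-d` convention of interval merge tools;
`filter_min_length` keeps the boundary (length ≥ minimum). Metaprofile
positions that fall off a chromosome are missing values excluded from column
means. The scaled-body mode resamples each element body to a fixed column
count and, for stranded profiles, reverses minus-strand rows so "upstream"
is always 5′ of the element; pooling across strands therefore requires
symmetric flank widths.

## Knockout-background ChIP correction

The model: observed control coverage = library scale × (specific +
nonspecific + base), KO coverage = library scale × (nonspecific + base),
with the nonspecific component (promoter-like peaks) identical in
expectation across conditions. Two scaling routes put samples on a common
scale before subtraction:

* **Spike-in RPM** — `factor = 1e6 / spikein_reads`; valid when spike-in
  recovery tracks library scale.
* **Common-peak** — peaks are called on the merged control and merged KO
  tracks (runs of at least two bins above `median + 3·1.4826·MAD`; the
  two-bin minimum exists because single-bin Poisson excursions are not
  peaks), a control peak counts as *common* when KO peaks cover at least
  25% of its length (reciprocality stops a broad specific domain touched by
  one stray KO bin from entering the scaling set), and factors equalize
  read totals over the top 10 000 common peaks ranked by combined count:
  `factor_i = mean_j(T_j) / T_i`.

Replicates are merged by summation after scaling; the corrected track is
`max(0, control − KO)` per bin (clipping optional). Factors are invariant
under a uniform rescaling of all inputs, so corrected signal scales exactly
with the data.

**Genome fraction marked.** The corrected track is re-binned to 10 kb by
mean; a histogram of `log1p(signal)` (100 equal-width bins, 3-bin
moving-average smoothing) is searched for its two highest local maxima, and
the threshold is the minimum-frequency bin strictly between them (leftmost
on ties). The valley must dip below half the smaller mode's height;
otherwise the distribution is declared unimodal and an error is raised
rather than returning an arbitrary threshold.

**Associations.** Compartment signal assigns each 50 kb bin to the
compartment covering the majority of it and reports a two-sided rank-sum
test. Gene-quartile signal computes per-gene body signal density, splits
genes into expression quartiles, normalizes by the *median* of the top
quartile (chosen over the mean; medians are robust to the handful of
extreme gene bodies) and reports a Kruskal–Wallis test. Profile similarity
is Spearman correlation between averaged profile vectors with
average-linkage clustering on 1 − ρ; zero-variance profiles yield missing
correlations and are excluded from clustering.

## Initiation zones

The peak caller used on synthetic data thresholds at
`median + z·1.4826·MAD` (z = 3) over all genome bins and keeps runs of at
least 5 kb — a stand-in for broad-peak calling on real data, whose output
would enter `call_zones` the same way. Zones are the union of peaks from
every sample, merged within 10 kb, kept at ≥ 20 kb.

**Differential statistic.** With the study's two replicates per condition,
dispersion cannot be estimated stably, so the per-zone p-value is the exact
conditional binomial test of the Poisson rate ratio on pooled raw counts
(`k_t` of `k_t + k_c` successes at `p0 = L_t/(L_t + L_c)` where `L` are
library sizes); with ≥ 3 replicates per condition a Welch t-test on log2
normalized counts replaces it. Concentrations are
`log2(mean normalized count + 1)` (counts normalized to the mean library
size; +1 stabilizes empty zones); the classification gates are
concentration ≥ 7 in at least one condition, |log2FC| ≥ 0.7,
BH-FDR ≤ 1e−10. Zones with zero counts everywhere get missing statistics.
The library-size normalization slightly deflates KO fold changes when the KO
gains genuine signal (its library grows); at the simulated effect sizes this
costs ≈ 0.1–0.2 in log2FC and does not move any class boundary.

**Hyperactivation.** The strongest half of constitutive zones is compared
across conditions by a *paired* Wilcoxon signed-rank test on per-zone
normalized counts. Pairing is essential: between-zone amplitude variation is
much larger than the ~1.3× hyperactivation factor, so an unpaired rank-sum
comparison has almost no power at realistic zone counts.

**Permutation enrichment.** The observed statistic is the total number of
features overlapping the query regions. The null redraws |query| regions
without replacement from a background set (for zone classes: the
constitutive+deactivated central windows) or, for genome-wide questions,
places length-matched regions uniformly (chromosome chosen proportional to
length). The one-sided p-value carries the +1 correction, so the smallest
attainable value is 1/(n+1); n = 5000 by default and every call records its
seed.

## Replication timing

`RTI = (e − l)/(e + l)` on depth-normalized counts is the unique symmetric
ratio statistic with range [−1, 1]; it is exactly ±1 when one fraction is
empty and missing when both are. Depth normalization scales the early and
late fractions to equal totals — no quantile normalization, so global
differences survive, but note that equal-total scaling absorbs a genuine
genome-wide *mean* shift of the program (it re-centers each condition); per-
bin differences on top of the global mean are what the differential test
sees.

**Per-bin test.** With ≥ 3 replicates per condition, Welch's t-test across
replicate RTIs. With exactly two — the study default — the pooled-variance
t-test (df = 2) is used instead: the Welch–Satterthwaite degrees of freedom
collapse toward 1 whenever one condition's two replicates happen to agree
closely, producing a near-Cauchy null whose p-values cannot reach stringent
FDR levels no matter how strong the effect. Bins require |ΔRTI| > 0.2 and
BH-FDR < 0.01; bins with a missing RTI in any replicate are excluded. A
ΔRTI-only mode exists for single-replicate data but must be requested
explicitly. Degenerate bins with zero variance in both conditions get p = 1
(no difference) or p = 0 (deterministic difference).

**Regions and transitions.** Adjacent flagged bins with the same ΔRTI sign
merge; direction is *anticipated* when mean ΔRTI > 0 (KO earlier). A region
sits in an early/late transition when the control RTI is strictly monotone
across (one bin upstream, region-center bin, one bin downstream); regions at
chromosome edges are classified false with a warning. Element-level RT is
the log2 early/late ratio of counts in the 50 kb window around the element
midpoint (regional) or over the element extent only (local), with a
configurable pseudocount (default 1 normalized count).

**Flattening.** The through-origin total-least-squares slope for pairs
(x = control RTI, y = KO RTI) is
`s = (S_yy − S_xx + sqrt((S_yy − S_xx)² + 4 S_xy²)) / (2 S_xy)`; it treats
both axes symmetrically and equals c exactly when y = c·x. When the KO also
carries a local anticipation term the planted global relation is no longer a
pure line through the origin, and the fitted slope sits below the flattening
factor; the slope-recovery check therefore runs on a simulation with the
anticipation term off, while the default-condition slope is reported as its
own quantity.

## Sequence features

Nucleotide content is computed per 5 bp bin as a percentage; ambiguous bases
are excluded from the denominator (fully ambiguous bins are missing), so
percentages over unambiguous sequence sum to 100. Poly(dA)/poly(dT) tracts:
a position is marked (score 100) iff it carries the target nucleotide and
lies inside some 20 bp window with ≥ 75% of that nucleotide. Scanning
fixed-length windows suffices (any longer qualifying tract contains
qualifying 20-mers), and restricting marks to target positions keeps a pure
minimal tract scored exactly over its own extent. One consequence worth
knowing: a 19 bp pure run is still marked, because it sits inside a 20-mer
at 95% purity — the ≥ 75% rule, not run length alone, decides. N bases count
toward window length but never toward the target. A- and T-tracts are
separate masks (their union is available); masks are per-base, with 5 bp
max-aggregation for joint display with content tracks. An exhaustive-window
oracle in the tests defines correctness for the scanner.

## The synthetic study

Defaults describe two 20 Mb chromosomes with alternating 2 Mb early/late
domains that double as A/B compartments; the latent timing program is
`r(x) = 0.45·sin(πx / 2 Mb)`, positive over A. What is planted, and why
these magnitudes:

* **Marked domains** — 40% of the genome in 100–500 kb blocks on a 10 kb
  grid, placed with 0.8 bias into A domains; specific ChIP rate 20
  reads/kb-bin over base 2. The planted fraction is exact by construction so
  fraction-recovery error is attributable to the estimator.
* **Nonspecific peaks** — 200 shared promoter-like 2 kb peaks at 120
  reads/bin, placed at gene starts at least one 10 kb block away from
  marked domains (otherwise a called control peak can merge with a specific
  domain and corrupt common-peak scaling). Peak height is set high enough
  that the clipped-noise residual after subtraction stays a small fraction
  of the peak level.
* **Genes** — 400 genes (2–20 kb) in A domains with lognormal expression.
* **TE catalog** — 300 background LTRs (100–1000 bp, strand Bernoulli(0.5),
  0.8 biased to B domains), 300 SINEs in A domains, plus activated LTRs:
  5-element clusters under each of 8 de novo zones and 48 solo elements in
  late bins. LTR bodies have AT 0.40, 200 bp flanks AT 0.70, and each flank
  carries one planted 24 bp tract (poly(dA) 5′, poly(dT) 3′, mirrored on
  minus-strand elements) built with every 8th base off-target so that every
  20-mer inside it is ≥ 75% pure — planted tracts are detectable by
  construction.
* **EdU-HU zones** — 32 constitutive (120–300 kb) and 4 deactivated zones in
  early domains, 8 de novo zones (80–160 kb) over LTR clusters in late
  domains, separated by ≥ 50 kb so called zones map 1:1 to planted ones.
  Plateau amplitudes are lognormal (σ = 0.4) around 30 reads/bin over
  background 5, clipped to [0.8, 3]× so no planted zone sits at the peak
  caller's detection threshold. The KO multiplies the strongest half of
  constitutive zones by 1.3, adds de novo plateaus with extra signal at LTR
  bodies, and reduces deactivated zones to 25%.
* **REPLI-seq** — per 50 kb bin, total reads Poisson(20 000) split
  Binomial(N, (1+r)/2) into early/late, two replicates; the RTI estimator is
  unbiased for r under this mapping. The KO program is `0.7·r` everywhere
  plus +0.4 at bins overlapping activated LTRs. Amplitude 0.45 with
  flattening 0.7 keeps the flattening-induced |ΔRTI| (≤ 0.135, plus ~0.034
  absorbed global shift) below the 0.2 gate, so only anticipated bins are
  flagged; the depth gives the two-replicate pooled t-test enough
  signal-to-noise to clear FDR < 0.01 at the planted effect size.

Noise is Poisson for coverage and Binomial for the early/late split — the
simplest models consistent with count data; per-sample lognormal
library-size jitter (σ = 0.1) and spike-in counts with small independent
jitter exercise the normalization machinery. All draws flow from one seed
through named substreams, so every output is reproducible byte for byte.

**What the synthetic validation does and does not show.** Passing tests
demonstrate that the estimators recover what they claim to measure under
the stated noise model, that the permutation test is calibrated, and that
the pipeline is deterministic. The generator does not model read-level
artifacts (mappability, GC bias, duplicates), overdispersion beyond Poisson,
realistic repeat families, partial knockouts, or cell-cycle heterogeneity —
on real data the same code runs, but effect sizes, depth requirements and
the FDR behavior of the two-replicate test will differ, and the
concentration/FDR gates should be revisited against library depth.

## Problem sizes

The default study (2 × 20 Mb, 1 kb coverage bins, 50 kb timing bins) runs
every analysis in seconds to a few tens of seconds on one CPU. The
end-to-end determinism check and the file-based examples use a
proportionally scaled 2 × 5 Mb configuration (`SyntheticConfig.scaled_to`),
which exercises identical code paths; determinism does not depend on
problem size.
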