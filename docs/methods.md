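# Methods

This note documents the statistical procedures implemented in `meklchip`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical decisions that matter for
reproducibility.

## Analysis model

### Relative methylation

Each hybridization yields an input channel `I` and a methyl-enriched
channel `E` per probe. Relative methylation is the normalized log ratio
`M = log2(E/I)`: enrichment of a probe's fragment by methyl-CpG capture
raises `E` relative to `I`. `M` is a *relative* quantity — the method
cannot measure absolute or single-CpG methylation.

### Signal score

Hybridization quality is the fraction of genomic probes whose
input-channel intensity exceeds the `background_quantile` (default 0.90)
of the anti-genomic probes — probes matching no genomic sequence, which
report pure background. The rule-of-thumb pass threshold is 0.85.
Samples below it are flagged, not dropped (dropping is an explicit
option): a flag is a QC observation, removal is an analysis decision.
If genomic and background intensities were drawn from one distribution
the score would estimate `1 − background_quantile` (≈ 0.10), which the
tests verify.

### Dye-bias correction

Two-channel arrays show an intensity-dependent dye bias: the M-vs-A trend
("banana") visible on control probes that should have `M = 0`. The
correction fits the trend on control probes only and subtracts it from
every probe's M, reconstructing both channels from `(A, M_corrected)` so
that each probe's A is preserved exactly.

Two trend estimators are provided:

* `method="spline"` (default): ordinary least squares onto a cubic
  B-spline basis with 8 interior knots at quantiles of the control A
  values, constant extrapolation beyond the control range. Because OLS is
  a projection, correcting an already-corrected sample is a no-op to
  machine precision — a property worth having in a pipeline that may be
  re-run over partially processed data, and one no genuine local
  smoother has.
* `method="lowess"`: classic locally weighted regression
  (statsmodels, degree 1, `it=0` for determinism) with window fraction
  `span` (default 0.4).

Both reduce the simulator's injected bias on control probes to well
under 0.05 log2 units; the spline is the default because of its exact
idempotence.

### Quantile normalization

Between samples, the M matrix is quantile-normalized: every column is
mapped onto the across-sample mean of the sorted columns. Tied values
receive the mean of the reference values at the tied positions (the
behavior of `limma::normalizeQuantiles(ties=TRUE)`, against which the
implementation is tested). Ties are detected with a small tolerance
(`atol 1e-12`, `rtol 1e-9`) so that values differing only by
floating-point round-off are still averaged together; without this the
output on heavily tied data would depend on sub-ulp noise. Normalizing
the M values (rather than the two channels separately) is the default
because M is the quantity the downstream t statistics use; a
`normalize_channels_separately` switch provides the alternative.

Note a consequence of tie averaging: on inputs with ties the columns'
value multisets are equal only up to the tie groups. On continuous
(tie-free) data the multisets are identical to machine precision.

### Clustering and genome-weighted smoothing

Genomic probes are grouped into clusters: consecutive probes on one
chromosome with start-to-start gaps ≤ `max_gap` (default 300 bp, the
typical sonication fragment size — a fragment spans neighboring probes at
this scale, so their signals are not independent). Within a cluster each
probe's M is replaced per sample by a triangular-kernel weighted mean
over probes within ±`window` bp (default 300): weight 1 at the probe,
linearly decreasing to 0 at the window edge. The triangular kernel keeps
one weighting convention with the local CpG density definition.
Smoothing never crosses cluster boundaries and leaves singleton clusters
unchanged; it never increases the probe-averaged across-sample variance.

### T-DMR calling

Per probe, a pooled-variance two-sample t test between tissue groups on
smoothed M, two-sided p from the t distribution with `n1+n2−2` degrees of
freedom. Degenerate probes (zero pooled variance) get `t=0, p=1` when
the means agree, and the smallest positive double (flagged) when they
differ. Within each cluster, maximal runs of consecutive probes with
`p < p_cutoff` (default 0.005) and a common t sign become regions; runs
with fewer than `min_probes` (default 3) members are discarded. The
region span is half-open, from the first member probe's start to the last
member's end.

Region-level p is a pooled-variance t test on the per-sample region means
of smoothed M (same df). A permutation alternative (within-cluster probe
shuffling, add-one empirical p on the region area) is available via
`region_p_mode="permutation"`. Regions are ranked by ascending region p,
ties by descending area `Σ|t|`, then coordinates.

No multiple-testing correction is applied by default — the calling rule
is a raw per-probe cutoff; a Benjamini–Hochberg q-value column is emitted
for information only.

### CpG landscape

For a region sequence: `CpG O/E = N_CpG/(N_C·N_G)·L` with N bases
excluded from all counts and from L; sequences with no C or no G return
0 with a degeneracy flag rather than raising, so batch annotation never
aborts. Regions with O/E > 0.6 are flagged island-like.

Local CpG density of a nucleotide: the sum over CpG sites (anchored at
the C; CpG is palindromic so strand is ignored) at offset `d`,
`|d| ≤ half_window` (default 300, inclusive at both ends), of weight
`1 − |d|/half_window`. A region's density is the mean over its
nucleotides, windows truncated at chromosome ends.

### Low-input concordance

Regional ΔM (mean over member probes of the group-mean M difference,
groups may be single samples) is computed for the reference regions in
each low-input run. The observed Pearson correlation (Spearman optional)
between reference and low-input ΔM vectors is compared with a null from
`n_perm` random re-pairings of the vectors (region-level shuffling; the
analyzed unit is the region — probe-level shuffling is achieved by
feeding probe-level ΔM vectors to the same function). Regions are labeled
`verified` when every low run reproduces the reference ΔM sign,
`dropout_1` / `dropout_2plus` otherwise; a low-run ΔM of exactly 0 has no
direction and counts as a disagreement, with its own counter.

### QPCR checkpoints

`ΔCt = mean Ct(tissue1) − mean Ct(tissue2)`, fold enrichment `2^ΔCt`
exactly. The orientation is explicit in every call: a locus
hypermethylated in tissue2 amplifies earlier there (lower Ct), giving
fold > 1. Pass rules: strictly greater than the threshold (default 2)
for hypermethylated control loci; a symmetric band
`|log2 fold| < log2 threshold` for equal-methylation controls.
Replicate dispersion is summarized as the SEM of replicate-wise folds —
a deliberate simplification; no mixed-effects modeling and no
amplification-efficiency or standard-curve correction.

## The synthetic-data generator

The simulator provides ground truth the real experiment cannot: planted
DMR locations, directions, and effect sizes.

* **Genome**: a two-state first-order nucleotide process. After a C the
  next base is G with probability 0.20 inside designated islands
  (CpG O/E ≈ 0.85) and 0.003 in background (O/E ≈ 0.01, a CpG desert);
  otherwise bases are equiprobable. Islands (default 2 kb) are placed one
  per equal-width block, covering `island_fraction` of the genome.
* **Probes**: 50-mers every 35 bp, kept only when the footprint fully
  contains a CG — CpG-driven tiling, so probes concentrate on islands.
  2000 control and 2000 anti-genomic probes are appended.
* **Truth**: DMRs are planted on islands, methylation 0.9 vs 0.1 between
  tissues (baseline 0.3 elsewhere, identical across tissues). Directions
  are a random but exactly balanced split — a strongly imbalanced split
  would shift null probes under quantile normalization, since planted
  probes are a sizable fraction of this small array (a real 2.1M-feature
  array does not have this problem, and real tissue pairs show roughly
  balanced splits).
* **Intensities**: per-probe log-normal input baseline (log2 mean 10,
  SD 1) shared across samples; anti-genomic probes draw background
  (log2 mean 7, SD 0.7) in both channels. The enriched channel is input
  times a saturating capture ratio `g(x) = 0.2 + 3.8·x/(x+2)` with
  `x = methylation × CpG count` — bounded, monotone, one shape
  parameter. With the defaults the planted regions have ΔM ≈ 1.6 log2
  units.
* **Dye bias**: an additive half-sine bump in M over the A range [6, 14],
  default amplitude 0.4 — the artifact the correction stage must remove.
* **Low input**: per-channel multiplicative log2 noise SD rising as input
  mass falls (0.20 / 0.35 / 0.45 / 0.60 at 250 / 50 / 25 / 10 ng) plus a
  per-probe probability (0 / 2 / 5 / 8 %) that the enriched channel
  collapses to background (capture dropout). These values are the
  package's chosen study conditions: no published noise measurements
  exist for this assay, so they were set once to give a clearly
  detectable effect at high input and visibly degraded, but not
  destroyed, signal at 10 ng.

**What the simulator does not emulate** — and therefore what passing
tests do not establish about real arrays: fragmentation-size and ligation
chemistry, PCR duplication or sequence-specific amplification bias,
spatial artifacts, probe cross-hybridization, and probe-sequence effects
beyond the CpG count. Real low-input arrays also show probe-level
reproducibility structure (the same probes failing across runs) that the
independent-noise model lacks; simulated low-input concordance is
correspondingly cleaner than published experience (correlations ≈ 0.99
and near-100% verified regions at the demo's effect size, versus ~0.6–0.8
and ~60% in real tissue comparisons). The demo's false-call rate also
depends on its CpG-desert background keeping null probe clusters sparse;
on a denser tiling, a raw `p < 0.005` cutoff yields proportionally more
false regions.

## The demo conditions

The reference demo (used by the worked example, the acceptance tests,
and `scripts/acceptance.py`) is a 2 Mb genome at `island_fraction` 0.06
(~60 islands), 50 planted DMRs, a 3v3 high-input reference at 250 ng,
and three 1v1 low-input runs (10/25/50 ng), with 1000 permutations for
the concordance null. This size keeps a complete end-to-end run within a
few seconds on one CPU while leaving ~10 probe-dense null islands and a
CpG-sparse background as false-positive opportunities.

## Numerical choices

* Coordinates are half-open 0-based everywhere, including BED output;
  strand is ignored (CpG is palindromic).
* Intensities are floored at 1.0 before logs (logged when applied).
* Floats are written as `%.10g`, making writer/reader round trips exact
  to below 1e−9 and repeated runs byte-identical.
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); derived stage seeds stay below 2^31.
  Preprocessing and calling contain no randomness at all.
* BED scores are `−log10(region p)` capped at 320 (p underflow).
* Ranking ties break by descending area, then coordinates — fully
  deterministic.

## Known limitations

* Region-level p values from per-sample region means are
  anti-conservative when member probes are few and noise is correlated
  by smoothing; they are meant for ranking, not inference.
* The t-based calling assumes equal group variances (pooled); with 3v3
  designs a Welch variant would be underpowered anyway.
* Quantile normalization assumes comparable global M distributions
  between samples; grossly asymmetric methylation differences violate
  this (see the balanced-directions note above).
* The smoothing kernel and the region-p definition are exposed as
  configuration because the original analysis software did not pin them;
  alternative choices change region boundaries at the margins.
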