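# Methods

## Model and procedure

The pipeline treats a methylation-enrichment sequencing library as a spatial
point process whose local intensity is proportional to methylated-CpG
density. Differential methylation between exposure groups is therefore a
difference in read *counts* per genomic window, tested under a count model:

- **Counting.** Windows of `window_size` (100 bp) at `window_shift` (50 bp)
  offsets; a read contributes to each window containing its leftmost aligned
  base (so exactly `window_size/window_shift` = 2 windows except within the
  first shift of a chromosome, a property the counting tests exploit for an
  exact conservation check). Anchor counting was chosen over fragment-overlap
  counting because the per-read contribution is constant, so window totals
  remain directly comparable across windows, and an optional
  `read_extension` is exposed for sensitivity analysis. Terminal windows
  shorter than the shift are dropped as degenerate duplicates of the previous
  window's tail.
- **Coverage floor.** A window is analyzed if ≥ `min_reads` (10) reads appear
  in ≥ `ceil(min_sample_fraction · n)` samples (25% → 3 of 12). The ceiling
  generalizes "25% of samples" safely to other sample counts.
- **Test.** Counts y<sub>iw</sub> ~ NB(r<sub>g(i)w</sub>·s<sub>i</sub>, φ)
  with Var = μ + φμ². One common φ is shared across windows: with four
  samples per group a per-window dispersion is hopeless, and a single φ keeps
  the test's df budget minimal. Group rates are fitted by Newton iteration on
  log r (concave objective; tolerance 1e−8, ≤50 iterations, means floored at
  1e−8 so all-zero groups remain finite); the two-rate vs one-rate
  likelihood ratio is referred to χ²(1). p-values gate at raw
  `alpha` = 0.05 — no multiple-testing correction enters the calling chain,
  because error control is delegated to the support/adjacency filters and
  the sex-contrast bound below; a Benjamini–Hochberg column is emitted for
  reporting only.
- **Dispersion.** φ maximizes the **Cox–Reid adjusted** profile
  log-likelihood summed over windows (group rates maximized out at each
  candidate φ, minus ½·log of the expected information of each fitted rate),
  over a 25-point log grid on [1e−6, 10] refined by golden-section search to
  relative tolerance 1e−4. The adjustment matters: the unadjusted profile
  estimator loses one df per fitted group rate per window and measured ~20%
  low (≈0.16 for a true φ = 0.2 with three groups of four), which inflated
  the null type-I error to ~0.10; with the adjustment, recovery is unbiased
  to ~1% and the null rejection rate at α = 0.05 sits at 0.05 ± 0.01.
- **Normalization.** Effective library sizes default to raw total input
  reads (fixed before any window filtering). A trimmed-mean-of-log-ratios
  adjustment (30% log-ratio trim, 5% abundance trim, reference = sample of
  median total, factors centred to geometric mean 1) is available as
  `normalization: tmm` for libraries with composition differences.
- **Support filter.** Per window, each sample's normalized count is compared
  with the midpoint of the two group medians; a final RAM needs
  ≥ max(2, ceil(`support_fraction`·group size)) samples of *each* group on
  their group's side. The midpoint-of-medians operationalization is
  threshold-free and tolerant of one outlier, and reduces to the intuitive
  "at least two samples" reading at n = 4.
- **Adjacency filter.** A preliminary RAM needs a second preliminary RAM of
  the same comparison and direction with |Δstart| ≤ `adjacency_stretch` −
  `window_size` (500 − 100 = 400 bp), i.e. both windows inside one stretch.
  This subsumes the immediate-flanking-window case (|Δstart| = 50). Where the
  narrative descriptions of the span rule differ (150/200 bp spans vs a
  500 bp stretch), the stretch is implemented as the operative rule and is
  configurable. Requiring the same direction is a deliberate choice: opposed
  directions within one region are biologically incoherent as a single RAM.
- **Merging.** Overlapping or book-ended same-direction final windows can be
  merged into regions (region p = min window p) for reporting; window counts
  remain the primary unit.
- **Annotation.** Shores/shelves are derived from *merged* CGIs so the
  flanks of nearby islands union rather than double-count; all sets are
  clipped to chromosome bounds and mutually disjoint by construction
  (re-derivation is idempotent). Window labels use any-overlap (≥1 bp) with
  fixed precedence — the derivation hierarchy for CGI contexts, and
  CDS-exon > 5′UTR > 3′UTR > TSS-up-1kb > TSS-up-5kb > intron > intergenic
  for gene features. "Upstream" is strand-aware; the TSS of a − strand gene
  is its interval end; the two TSS categories cover upstream flanks only.
  Genome-background feature shares are computed from the supplied annotation,
  not from any external table.
- **Promoters.** A window is promoter-assigned to every gene whose
  [TSS − 1500, TSS + 1500) interval it overlaps; multi-gene assignments are
  kept. The dose–response classes use only the two exposure-vs-control
  comparisons (the high-vs-low comparison is reported separately). Promoters
  with both directions in one comparison, or opposite directions between the
  two comparisons, are "mixed" and excluded from the six class counts.
  Classes count unique promoters (TSS regions); window counts are also
  reported.
- **Heatmap filter.** "Low reads in at least one exposure group" has no
  printed threshold anywhere, so it is tied to the pipeline's only stated
  read floor: a group's mean normalized count below `min_reads` / median
  effective size. The alternative admission is a ≥ `heatmap_fold` (5×) ratio
  between any two group means. Rows span TSS ± 1.5 kb in window-size bins,
  orientation-flipped for − strand genes.
- **Sex-contrast QC.** `sex_based_fdr` is literally the exposure calling
  chain invoked with the sex column as the grouping factor (one shared
  function, asserted by the tests), A = male, B = female. Autosomal calls
  are treated as false and sex-chromosome calls as true, so
  100·autosomal/total is an *upper bound* on the FDR — real autosomal sex
  differences, and exposure effects confounded with an uneven sex split,
  also land in the numerator. It is reported only as a bound, never as the
  FDR. A second check requires zero female-hypermethylated chrY windows.

## The synthetic-data generator

The generator emulates the study conditions end to end: 12 samples in three
exposure groups with the design's sex split (control 2M/2F, low dose 2M/2F,
high dose 1M/3F), ~200,000 single-end 80 bp reads per sample over a ~6 Mb
toy genome (autosomes of 2.75 + 2.5 Mb, chrX 0.5 Mb, chrY 0.25 Mb), CpG
islands placed as a Poisson process (mean spacing 40 kb, lengths
0.4–1.4 kb), and gene models seeded at 60% of CGIs plus a few intergenic
placements.

The methylation landscape is piecewise-constant over 500 bp tiles — the
analysis operates at 100 bp windows, so sub-window resolution would buy
nothing — with a jittered base level (0.35 ± 0.05). Planted effects occupy
one tile centered on an autosomal CGI, with direction (hyper/hypo) ×
dose class (monotonic, low-dose-only, high-dose-only) cycled across 30
regions and a 3× default multiplier (the plausible middle of the 2–4× range
for enrichment counts). Low-dose-only effects return exactly to the control
level at the high dose, the non-monotonic signature.

Read sampling weight per tile = methylation level (for the sample's group)
× CG-density weight × sex factor. The CG-density profile is sharply peaked:
CGI tiles weight 60, the 0–4 kb flanks 1.5, open sea 1, then a single scale
factor on all CGI-neighborhood tiles is solved analytically so that the
expected read depth inside CGI ± 4 kb exceeds outside by exactly the
configured fold (2.3 by default), accounting for tiles that straddle the
neighborhood boundary. The peaked core is what gives planted CGI regions
the ≥50× regional coverage at which the recovery benchmarks are defined,
while the genome-wide fold stays at its configured value; empirically the
realized fold is within ~1% of target at ≥100k reads. Sex is modeled as
chrX dosage (female 2×) plus chrY weight in males only, with a 0.5% female
leak. The sex chromosomes are deliberately a small share of the genome
(~8% + 4%, echoing the mouse karyotype): an oversized chrX would depress
the female autosomal read share enough to masquerade as autosomal
differential methylation under raw-total normalization — a pure
library-composition artifact we measured at chrX = 25% and eliminated by
restoring realistic proportions. Per-sample library sizes scatter
log-normally (sd 0.1 in log10) around the configured depth; reads start
uniformly within their tile, strands are random, and each sample draws from
a stream seeded by master + sample index (kept below 2³¹).

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: fragment-length and insert-size structure,
sequencing error and mapping ambiguity, per-CpG resolution, copy-number
variation, batch effects, biological replicate heterogeneity beyond the NB
dispersion, and genome-scale window counts (a 6 Mb genome yields ~10⁵
windows, not ~10⁷). Benchmarks on it measure the pipeline's statistical
behaviour under its own model assumptions, at stated effect sizes and
coverages, not field performance.

## Numerical choices and degenerate inputs

- Coordinates are 0-based half-open everywhere internally (BED convention);
  human-readable reports state the convention.
- Means are floored at 1e−8 and rates at 1e−12; an all-zero group fits at
  the floor with a finite statistic. p-values are clipped into (0, 1].
- The LRT is clipped at 0 (profile optima can be microscopically negative
  through convergence tolerance).
- Ties in the support filter are strict (a sample exactly at the midpoint
  supports neither side).
- Dispersion search returns the lower grid bound when the likelihood still
  rises toward φ → 0 (effectively Poisson data).
- Outputs are written deterministically (sorted rows, fixed float format);
  rerunning with identical inputs reproduces byte-identical files. The CLI
  accepts `--threads` for interface compatibility; computation is
  vectorized single-threaded numpy, so results are trivially independent of
  the value.
- Invariances guaranteed and tested: group-swap antisymmetry (log2FC flips,
  p invariant), invariance to the units of library size, normalized-mean
  invariance under count-and-size rescaling of a sample, filter
  monotonicity/idempotence, and order independence of the filter chain.

## Benchmark scales

The test suite and the reproduction script use the study-condition fixture
(12 samples × ~200k reads, 30 planted regions) once per session, 5,000-window
matrices for the null-calibration and dispersion-recovery measurements, and
10 simulation replicates where a median is quoted. On one CPU the full test
suite runs in under a minute and the reproduction script in a few seconds.

## Known limitations

- One common dispersion genome-wide; no tagwise/trended shrinkage or
  quasi-likelihood F-test. With n = 4 per group this is a deliberate
  bias-variance trade, but windows with atypical dispersion are mis-weighted.
- Sex is not a model covariate (matching the emulated design, whose
  high-dose group is 1M/3F); sex-linked windows must instead be recognized
  via the sex-effect regions, and an uneven sex split leaks a small
  composition bias into exposure contrasts.
- The support filter's midpoint rule is one of several defensible readings
  of "methylation change in at least two samples"; it is the package's
  definition, not a community standard.
- Raw-total normalization ignores composition differences; use `tmm` when
  libraries differ in global makeup.
- The empirical FDR bound is exactly that — an upper bound whose tightness
  depends on how much true sex-linked and confounded signal lands on
  autosomes.
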