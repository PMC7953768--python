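# Methods

## Data model and coordinates

A CpG site is keyed by the 1-based coordinate of its forward-strand C;
the reverse-strand C of the same palindromic CpG sits at `pos + 1`, and
the canonical TSV reader merges the two strand rows under that
convention. Per cohort the package keeps four integer count matrices
(methylated/total × forward/reverse) of shape (sites × samples), aligned
with a sorted site table. The tumor and normal cohorts of a study are
paired and share sample ordering; no per-sample pairing beyond order is
modelled.

## Site calling

The null hypothesis at each CpG is that forward- and reverse-strand
methylation levels are exchangeable across samples. Per site:

1. **Coverage filter.** Sample `s` is informative iff both strands carry
   at least `min_reads` (default 4) reads. The filter is per sample, not
   pooled, because the paired signed-rank test needs per-sample pairs; a
   pooled variant is available behind `pooled_coverage`.
2. **Test.** The informative differences `f_is − r_is` go to a paired
   Wilcoxon signed-rank test: zero differences discarded, absolute values
   ranked ascending with average ranks on ties, `W+` the rank sum of
   positive differences. For `n ≤ exact_threshold` (default 25, covering
   the 18-sample design) the two-sided p is exact, computed by
   generating-function convolution over the observed tied rank vector
   with the doubled-tail convention `min(1, 2·min(P(W≤w), P(W≥w)))`.
   Beyond that, a tie-corrected normal approximation with continuity
   correction is used. The exact/approximate switch is configuration, not
   data-dependent behaviour.
3. **Labels.** MU requires `p < alpha` **and** `mean(d) ≥ cutoff`; UM the
   mirrored condition. Significance alone never suffices — the
   mean-difference filter suppresses sites with statistically reliable
   but biologically small strand asymmetry. Sites with fewer than
   `min_samples` (default 6) informative pairs are NA: 6 is the smallest
   n at which the exact two-sided test can reach p < 0.05 (the minimum
   achievable p is `2^(1−n)`), so smaller n is untestable by
   construction rather than by convention.

The sign convention `mean_diff = forward − reverse` makes the MU label
agree with a positive mean difference; the test is two-sided, so the
orientation of the subtraction does not affect p-values.

Raw p-values are used by default. A Benjamini–Hochberg adjustment is
available (`bh_correct`) as plumbing; spatially-aware corrections are out
of scope.

## Clusters and taxonomy

Scanning testable (non-NA) sites in genomic order, maximal runs of MU/UM
sites of length ≥ 2 are clusters; length-1 runs are singletons. An NS
site breaks a run (it is positive evidence of strand symmetry); an NA
site does not, because it carries no evidence either way — a strict mode
(`na_breaks_runs`) is provided since the opposite reading is defensible.
No maximum gap is imposed by default (`max_gap=None`): RRBS CpG density
keeps runs locally dense, and the gap rule exists only for sensitivity
analysis.

Patterns are forward-strand-first with the reverse half the sitewise
complement (`MMM-UUU`, `MU-UM`, …). The reporting taxonomy is: 2-site
same-orientation clusters are regular pairs (MM-UU / UU-MM), 2-site
opposite-orientation clusters are polarity pairs (MU-UM / UM-MU), and
every cluster of ≥ 3 sites is "bigger", counted with the regular
clusters in the regular/polarity summary tables regardless of its
internal orientation mix. This is the only reading under which a full
pattern inventory containing mixed ≥ 3-site patterns (MMU-UUM, UMM-MUU,
…) reconciles with two-way regular/polarity totals, and the acceptance
suite checks that reconciliation explicitly. Cluster length is
`end − start` in bp over the CpG forward-C coordinates, exactly the
printed definition; adjacent CpGs are ≥ 2 bp apart so lengths are ≥ 2.

## Overlap classification

Cluster spans are closed intervals; touching at a single bp counts as
overlap. Relations are assigned with precedence exact >
contained_in_other > contains_other > other_overlap; containment
requires at least one endpoint strictly inside (identical spans are
exact). Counting is per cluster per cohort, which makes the two
containment columns legitimately asymmetric when one long cluster holds
several short partners. Properties enforced by tests: exact counts are
symmetric between cohorts, per-cohort relation counts partition the
cohort total, and the classification agrees with a quadratic all-pairs
oracle on random interval sets.

## Annotation

Promoters are strand-aware windows, default 2000 bp upstream and 0 bp
downstream of the TSS (`[tss−u, tss−1+d]` for + genes, mirrored for −),
clipped at position 1; "promoter" has no universal definition so the
extent is configuration. A hemi site is assigned to every gene body and
every promoter containing it (overlapping genes each count it); body and
promoter assignments are independent. Gene selection thresholds at
≥ `min_sites` (default 5) distinct hemi positions; the "shared" mode
counts positions hemimethylated in both cohorts at identical
coordinates, orientation-insensitive by default (a strict-orientation
switch exists). Family tags are an external two-column mapping; a small
static tag file for commonly reported cancer gene families ships with
the package.

## Statistical tests

All three tests are implemented in `hemimeth.stats` rather than
delegated, because their exact small-n behaviour defines site
testability; scipy's implementations serve as independent cross-checks
in the test suite. The two-proportion comparison is the pooled z-test
without continuity correction (its z² equals the Pearson chi-square of
the corresponding 2×2 table, a property the suite asserts to 1e-10).
The rank-sum test is exact by subset enumeration when `n1+n2 ≤ 20`
without ties.

## Synthetic cohorts

The generator emulates the study design: 18 paired samples, CpG islands
(default two chromosomes, 8+6 islands of 10/8 CpGs at 20 bp spacing),
per-strand negative-binomial coverage (mean 30, dispersion 5), 5%
dropout per (site, sample, strand), and background levels drawn once per
site from Beta(0.3, 0.3) — concentrated near 0 and 1, as bisulfite
averages are — shared between strands, samples and cohorts, so unplanted
sites differ only by binomial noise. Planted events draw per-sample
strand levels from effect betas, default Beta(18, 2) vs Beta(1, 19),
i.e. an expected strand difference of 0.85. The default event set covers
every taxonomy branch and all three cohort placements (tumor-only,
normal-only, both). Everything is deterministic given the seed.

What the simulation does *not* model: read-level bisulfite conversion
error, copy-number effects, sample heterogeneity in effect size, spatial
correlation of background levels along an island, and genome-scale site
counts. Passing recovery tests therefore demonstrate correctness of the
calling/clustering machinery under the declared generative model, not
performance on real RRBS data.

## Problem sizes and numerical choices

The acceptance computations use the published summary counts directly
(exact arithmetic) plus Monte-Carlo runs at the study-shaped conditions:
200 replicates of a planted 3-site cluster on a 10-CpG island for
sensitivity, and 20 null replicates of 30 sites for the false-positive
rate — sizes chosen so the whole suite completes in seconds while the
binomial standard error on a ≥ 95% sensitivity bound stays below 2
percentage points. Exact-test tails are computed by integer convolution
(ranks doubled to absorb half-integer average ranks), avoiding floating
cancellation; degenerate inputs (all-zero differences, fully tied
rank-sum groups, pooled proportions of 0 or 1) return p = 1 explicitly.
Percentages in summary tables are rounded to two decimals; a zero
denominator reports an undefined percentage rather than 0.

## Known limitations

* Calls are per-cohort; no direct tumor-vs-normal differential test at a
  single site is provided (the cross-tab and overlap reports are the
  comparison surfaces).
* The gene-model reader takes one record per gene; when several
  transcripts imply different TSSs, isoform choice belongs to input
  preparation.
* Absolute site/cluster counts from the original cohort depend on the
  upstream alignment stage and are not reproducible from summary inputs;
  only derived proportions and the procedure's operating characteristics
  are.
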