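# Methods

`sclst` re-implements, as a tested pipeline on synthetic data, the analysis
used to score chromosomal instability (CIN) in single tumor cells profiled
by low-pass whole-genome sequencing (lp-WGS): binned copy-number calling,
large-scale transition (LST) counting, gene-level CNA annotation, and a
SMOTE + random-forest classifier of LST status. Because no patient data are
bundled, a forward simulator with oracle-computed ground truth stands in
for sequencing data at every stage.

## Coordinate frame and binning

Internal coordinates are 0-based half-open; BED is read/written natively,
SEG (1-based inclusive) is converted at the I/O boundary. The genome is
either the 22 GRCh37 autosomes at reference lengths (`hg19_autosomes`) or a
desk-scale toy genome (three 100 Mb chromosomes) for unit tests. Each
chromosome is tiled with fixed 500 kb bins (the last bin truncated). Bins
carry GC fraction, mappability and an ENCODE-style blacklist flag; a bin is
usable when it is not blacklisted and its mappability is at least 0.5. The
mappability threshold plays, at bin granularity, the role a read-level
mapping-quality cutoff plays upstream: regions with untrustworthy
alignment contribute nothing. GC and mappability are inputs or fixtures;
no FASTA is parsed.

## Forward model (synthetic data)

A cell's ground truth is its integer copy number along the genome: ploidy 2
plus additively composed events (floored at 0 copies). Event counts are
Poisson — one clonal set shared by the cohort (mean 6) plus per-cell
private events (mean 20) — with lengths log-uniform on 1–15 Mb and deltas
drawn from {−2, −1, +1, +2} with probabilities {0.1, 0.5, 0.3, 0.1} (a
slight loss excess, as in triple-negative breast cancer copy-number data).
These defaults emulate, on the autosome frame, single-cell cohorts with
roughly 30 CNA calls per cell and LST counts spanning about 0–18 with a low
median — the regime reported for patient-derived circulating tumor cells.

Counts are emitted per bin with expectation proportional to copy number ×
GC bias × mappability, normalised to a fixed total depth (default 1,000,000
reads, comfortably above the 400,000-read QC floor). The GC bias is a
quadratic multiplicative curve centred at GC 0.45 — the simplest smooth
bias the correction stage must remove. Reads are drawn multinomially
(conserving depth exactly), then each bin is multiplied by a lognormal
whole-genome-amplification (WGA) factor with sigma `wga_dispersion`
(default 0.3; the WGA noise level is an engineering choice — no published
quantification exists for this protocol — and is deliberately on the noisy
end of plausibility) and re-rounded. Amplification dropout is modelled as
contiguous regions (not i.i.d. bins, because WGA failure is regional)
totalling `dropout_rate` of the genome (default 1%) with expectation scaled
by 0.05.

What the simulator does not emulate: read-level artifacts (chimeras,
duplicates), structured mappability along real chromosomes, correlated
noise between neighbouring bins beyond dropout, replication-timing bias,
and subclonal mosaicism within a cell. Passing tests therefore demonstrate
correct recovery of the simulator's data model, not performance on real
libraries.

### Ground-truth annotations

Each truth profile stores its constant-CN segments plus three oracle
quantities: `true_aberrant` (any non-baseline region > 12.5 Mb, or
non-baseline regions cumulatively > 37.5 Mb), `true_gene_states`
(majority-overlap copy state per panel gene, sign-collapsed to −1/0/+1) and
`true_lst`. The truth LST is deliberately the *state-based* metric — copy
number collapsed to loss/neutral/gain, boundaries snapped to the analysis
bin width, sub-3 Mb runs merged, then the two-flank ≥ 10 Mb rule — so that
truth and pipeline estimate measure the same estimand; raw integer-CN
transitions would count breaks (e.g., between CN1 and CN0 runs) that no
three-state caller can see.

## Per-cell pipeline

**QC.** Cells with fewer than 400,000 total reads are excluded; when a
genomic integrity index (a 0–4 wet-lab WGA quality score) is supplied,
cells below 2 are excluded as well. The index is metadata only — the
package never computes it.

**Normalization.** Unusable bins are masked (a profile with fewer than 100
usable bins is rejected as unreliable). Log2 counts (floored at 0.5 reads)
are GC-corrected by aligning, across GC deciles, each decile's *modal* log
count — the kernel-density mode on a robust MAD bandwidth, evaluated at the
sample points so the transform is exactly shift-equivariant (and hence
exactly idempotent). The mode rather than the median anchors each decile on
its dominant copy state: a decile partially covered by a genuine large loss
would drag a median and mis-scale every bin that shares the decile. The
corrected log2 values are centred on their median, making the usable-bin
median log2 ratio exactly zero. The per-bin noise scale is estimated
robustly from within-chromosome consecutive-bin first differences
(MAD/√2); bins deviating from a 15-bin rolling median by more than 4 of
these SDs are flagged as residual outliers.

**Segmentation.** Circular binary segmentation, re-implemented: for each
chromosome the statistic is the maximum two-sample |t| over all "arcs"
[i, j) against their complement (minimum piece 2 bins), which places up to
two breakpoints at once — the circular family is what lets a chromosome
with several same-sign events be split at all. Significance is a seeded
within-segment permutation test (α = 0.01, 1,000 permutations) evaluated
sequentially: permutation chunks stop as soon as the accept/reject decision
against α is settled, or when the observed statistic exceeds 1.5× every
permuted value seen (≥ 48 permutations), or after 2/α permutations without
a single exceedance. For break detection only, values are winsorized at 3
robust SDs around a rolling median — otherwise isolated dropout/zero-count
spikes dominate the permutation null and mask genuine single-copy steps;
segment means are always computed from raw values. Accepted breakpoints are
locally re-fitted (minimum residual sum of squares within ±3 bins), which
removes a systematic edge-bin absorption bias, and adjacent segments whose
means differ by less than 0.1 are merged back.

**Calling.** A segment is gain when its mean log2 exceeds +0.3, loss below
−0.3 — thresholds placed between noise and the single-copy closed forms
(+0.585 for 3:2, −1 for 1:2) since no published thresholds exist for this
stage. Two robustness rules apply: thresholds are taken relative to the
cell's modal copy-state level (length-weighted kernel mode of segment
means; median centring leaves loss-heavy genomes with a positively biased
baseline), and a non-neutral call must also clear 3 standard errors of the
segment mean (segmentation selects extreme arcs, biasing marginal means
across any fixed threshold). Segments in which more than half the member
bins lie over 4 robust SDs from the segment mean are forced neutral (the
residual filter lifted to segment level). All chr19 segments are forced
neutral in call output: chr19's GC-driven coverage depression in amplified
single-cell libraries produces spurious deletions. The exclusion applies to
CNA calls only; a flag extends it to LST counting (default off).

**Aberrancy and counting.** A cell is aberrant when any gained/lost region
exceeds 12.5 Mb or the gained/lost regions cumulatively exceed 37.5 Mb.
CNA counts are the numbers of gain and loss calls.

## LST metric

Interior call segments shorter than 3 Mb are merged into the neighbour with
the numerically closer state (ties to the left), then equal-state
neighbours coalesce; the sub-3 Mb smoothing follows the original LST
methodology and can be disabled. Within each block — whole chromosomes by
default, p/q arms when centromeres are supplied — every adjacent pair of
segments with different states counts as one LST when *both* segments span
at least 10 Mb (the two-flank reading of the definition). Cells are
LST-high at 3 or more (the published median-derived cutoff); a cohort-median
mode re-derives the threshold instead. Replicate reproducibility mirrors
the cell-line replicate design: per-group mean, sample SD, CV = SD/mean,
and a one-sample two-sided t-test against an explicit reference value
(the published table's test is consistent with a pooled grand mean, but
that is an inference, so the reference is always an explicit parameter).

## Gene-level analysis

CNA calls are projected on the gene panel by majority overlap (ties broken
by the call with larger |mean log2|), giving a cells × genes matrix in
{−1, 0, +1}. The shipped panel holds the 15 named HRD-related and TNBC
driver genes at hg19 coordinates and is user-replaceable; the full 39-gene
panel is not reproduced. HRD-loss flags mark loss in any of RAD51, BLM,
WRN. Group comparisons use Welch's t-test for CNA counts and a two-sided
Fisher exact test (point-probability summation) for the flag-by-class
table. Over-representation analysis takes the panel as the universe,
counts a gene as altered when non-neutral in more than half the LST-high
cells, and applies Fisher + Benjamini–Hochberg across gene sets. These are
generic re-implementations; no external pathway or annotation database is
queried.

## CIN classifier

SMOTE balances the classes by interpolating minority cells between nearest
minority neighbours (k = 5, λ ~ U(0,1)); because the covariates are ordinal,
synthetic coordinates are rounded to the nearest level (a neighbour-vote
mode is available). The forest is 500 CART trees (Gini, ⌊√p⌋ features per
split) bagged in-package so that per-tree bootstrap masks are available;
out-of-bag (OOB) error uses majority votes over each cell's OOB trees.
Variable importance is Breiman's permutation VIMP: the mean per-tree OOB
error increase when one feature's values are permuted, on the error-rate
scale (0.30 = 30 percentage points). Per-tree averaging matters: the
aggregate-majority-vote error barely moves when a partially redundant
feature is permuted, because flipping a few of 500 trees rarely flips a
majority. ROC/AUC (threshold sweep; trapezoid = normalised Mann–Whitney
statistic) is computed from OOB vote fractions **of the observed cells
only** — synthetic interpolants sit between real cells, are trivially
classified, and measurably inflate the AUC of even a null cohort — with a
percentile bootstrap CI over cells. No external test set exists in this
design; the reported AUC is a training-cohort OOB quantity and retains the
optimism inherent to oversample-then-evaluate workflows, which is why the
synthetic planted-signal AUC (~0.85–0.95) should be read qualitatively.

The feature-level cohort simulator plants `n_causal` genes whose losses
raise the log-odds of the LST-high label linearly (logistic link anchored
at P(high) = 0.2 with no causal loss and 0.8 with one); the causal loss
rate 0.3 makes the expected class balance ≈ 63% high, the imbalance seen in
CTC cohorts. A majority-style link was rejected on first principles: with
label probabilities confined to {0.2, 0.8} the Bayes-optimal AUC is exactly
0.80, which no honest evaluation can exceed. The null cohort is exactly
balanced with labels independent of all features.

## Numerical and reproducibility notes

- Every stochastic step takes a seed or `numpy` Generator; fixed-seed runs
  of the full pipeline are byte-identical (manifest checksums).
- Permutation p-values use the (1 + exceedances)/(1 + draws) convention.
- Zero-variance replicate groups off the reference report the smallest
  positive float rather than NaN.
- Degenerate inputs are errors, not silent passes: empty genomes, empty
  gene sets, single-class training labels, all-unusable grids, groups of
  size one.
- Problem sizes in tests and the acceptance script: recovery uses 50 cells
  on the hg19 autosome grid (~5,700 bins); replicate statistics use a
  six-chromosome 900 Mb genome; classifier checks use 120-cell cohorts and
  25 seeds. These sizes are the package's chosen desk-scale study
  conditions.

## Known limitations

- LST recovery: truth-vs-estimate mean absolute error is ~1.4 at the
  default noise level, but rank correlation saturates around 0.8–0.85.
  Three error sources dominate, all properties of 500 kb single-cell data
  at this noise level rather than fixable defects: ±1-bin boundary jitter
  flips events lying at the 10 Mb knife edge (boundary-jitter alone bounds
  the rank correlation near 0.94); clusters of sub-resolution (1–2 bin)
  events average into callable segments that the truth metric smooths to
  neutral; and WGA dropout is indistinguishable from true homozygous loss.
- The gain/loss thresholds, smoothing size and LST block definition are
  declared defaults, not values recovered from any published analysis.
- The classifier's AUC is an OOB training-cohort quantity (see above), not
  an external validation estimate.
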