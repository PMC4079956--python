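# Methods

## Read model and preprocessing

A small-RNA library read is modelled as `[5' adapter] + insert + 3' adapter`
with per-base phred(+33) qualities. Trimming finds, for the 3' adapter, the
*leftmost* position where a prefix of the adapter aligns with mismatch
fraction ≤ `max_mismatch_rate` (default 0.1) over an overlap of at least
`min_overlap` (default 6) bases; terminal partial overlaps count. A 5'
adapter, when configured, is removed first by the mirror-image rule
(rightmost matching end, i.e. maximal trim). Neither overlap nor mismatch
defaults are dictated by the protocol being modelled; 6/0.1 are the common
practical choices. Retention then requires 16 ≤ length ≤ 35 and arithmetic
mean phred ≥ 30 (strict ≥). The protocol's Methods and Results sections
state different short-read cutoffs (16 nt window start vs "< 18 nt"
discard); the 16–35 window is the default and the alternative is a plain
config override, not a second rule. Only phred+33 is accepted; qualities
above 42 abort parsing rather than being silently re-interpreted as
phred+64.

## IsomiR classification

`classify_against_mature` is a pure total function over (read, mature)
pairs returning the first category matched in the fixed precedence order
IDENTICAL → SHORTER_PERFECT (prefix/suffix, 1–5 nt short) →
END_SUBSTITUTION (equal length, one difference at first or last position)
→ ONE_EXTRA_BASE → TWO_EXTRA_BASES (2+0, 1+1 or 0+2 over the ends) →
INTERNAL_MISMATCH (one difference strictly inside). The precedence prefers
the most exact explanation; combined with the definitions it makes the
categories mutually exclusive by construction. Design choices made where
the category definitions leave room:

* extra bases are untemplated (any base) and end-located only; three or
  more extensions are unclassified at mature level and can only surface as
  precursor matches;
* the 1+1 split is allowed for two extra bases;
* precursor matching is exact substring, no mismatches — mismatch
  tolerance exists only at mature level;
* `N` never matches anything.

`assign_read` applies this per species tier (rat → mouse → human): the
winning category is the highest-precedence category achieved by *any*
mature in the tier; a unique winner yields a call, multiple winners mark
the read ambiguous and it is excluded from counting (never fractionally
allocated). A tier with no mature-level match tries its precursors; only a
tier that yields nothing lets the read fall to the next tier, which makes
the cascade monotone (later tiers cannot change earlier assignments). The
production path uses hash indexes over exact sequences, 1–5-nt
truncations, end-variant lookups and length buckets; it is an optimization
only and is tested for equality against a record-by-record scan and against
an independently written first-principles oracle over all variants of
random matures.

Terminal labelling order for a sample is primer-dimer (post-trim insert
< 16 nt) → miRNA cascade → other-ncRNA → exon → unaligned, so the class
totals partition the clean reads exactly. Unaligned reads cascade through
the dietary databases in wheat → corn → soybean order, then identical
leftover sequences are tallied to expose dominant contaminants.
Auxiliary-database matching is exact substring containment — a
desk-scale stand-in with defined semantics for a short-read aligner; the
`SequenceDB` interface isolates it so an aligner could be substituted.
BLAST-style hits elsewhere are accepted when aligned/query > 0.85
(strict inequality).

## Quantification

Counts are merged per miRNA across all isomiR categories (including
precursor) before normalization. The three normalizations are implemented
from their defining formulas rather than delegated to the R packages they
originate from, because the formulas *are* the subject here:

* **RPM** uses miRNA-mapped reads as denominator (as the defining formula
  states), not all clean reads.
* **Median-of-ratios** requires at least one all-positive row; an optional
  +0.5 pseudo-count rescues degenerate fixtures and is never on by default.
* **TMM** uses the published defaults: 30% two-sided trim on M, 5% on A,
  inverse binomial-variance weights
  (N<sub>j</sub>−k)/(N<sub>j</sub>k) + (N<sub>r</sub>−k<sub>r</sub>)/(N<sub>r</sub>k<sub>r</sub>),
  reference = sample whose 75th-percentile count fraction is closest to
  the mean of those, and factors rescaled to geometric mean 1. Rows with a
  zero in either sample are dropped pairwise; a sample sharing no positive
  rows with the reference gets factor 1 with a warning.

## Statistics

The Welch statistic is computed directly (t, Welch–Satterthwaite df,
two-sided p) so the zero-variance limits are defined: equal means → p = 1,
unequal means → p = 0 with a warning; the finite-variance path is
cross-checked against scipy in tests. The count-based test is the
conditional binomial: given K = K_a + K_b, p-value = P of outcomes at most
as probable as the observed K_a under Binomial(K, N_a/(N_a+N_b)) with
effective depths N; tests verify it against exhaustive enumeration.
Differential calls use FC = mean(treated)/mean(control) on the linear
normalized scale, encoded as signed fold change (r ≥ 1 → +r, r < 1 →
−1/r), with welch_log operating on log2(v+1). Significance is raw
p < 0.05 AND |FC| ≥ 1.5; no multiple-testing correction by default
(Benjamini–Hochberg is available behind a flag). Sample clustering uses
d = 1 − Spearman ρ (average ranks; a zero-rank-variance column gets ρ = 0
with a warning) and complete linkage, with columns sorted lexicographically
for deterministic ties.

## qPCR pipeline

"Undetermined" wells are missing data, never Ct-40 imputations — the
detection rule (Ct ≤ 32 in ≥ ceil(0.2·n) samples) already encodes
detectability. Normalizations: global mean (per-sample mean detected Ct
removed, grand mean restored), invariant set (same, but offsets from the
`invariant_k` = 10 complete-case assays of lowest across-sample variance,
falling back to all complete cases with a warning), and cyclic-to-reference
lowess (each sample's deviation from the per-assay mean profile regressed
on that profile, span 0.5, 3 robustness iterations, fitted curve
subtracted). Fold change is 2^(−ΔΔCt) from group mean Ct difference; the
Welch test runs on the per-sample normalized Ct values (not linearized),
matching standard TLDA practice of reporting FC and p separately. Assays
with fewer than 2 detected values in either group are reported
not-testable rather than silently dropped.

## Synthetic data

The generator emulates a gel-selected (16–30 nt insert) urinary library:
reads from every isomiR class, precursor fragments, other-ncRNA/exon
fragments, dietary contaminants, primer-dimers (adapter-adapter products
with empty insert) and uniform-random sequence, each wrapped with
adapters and N(mean Q = 38, sd = 2) qualities — the quality regime of a
modern instrument, so the Q ≥ 30 filter is exercised but not dominant.
Default adapters are fixed arbitrary 20-mers shipped with the package.
Precursor fragments are rejection-sampled until unclassifiable at mature
level, so truth classes and classifier categories are in bijection and
closed-loop tests are sharp. All randomness flows from one seeded
generator; byte-identical output given the seed.

Ct matrices are normal around group means with a per-assay baseline
N(26, 3) — the low-Ct regime a pre-amplified TLDA card produces — well
noise sd 0.5 by default, a true ratio r shifting treated means by
−log₂(r), and wells above a dropout threshold (default 35) emitted as
"Undetermined".

What the generator does *not* emulate: position-dependent sequencing
error, PCR duplication, ligation bias, and the empirically observed
14–60% unalignable fraction of mixed unknown origin in real urine
libraries. Passing closed-loop tests therefore demonstrates correctness
of the classification and statistical machinery under known composition,
not performance on real contaminated libraries.

## Problem sizes and calibration checks

The acceptance computations use: 100 random 18–25-nt matures with every
single-edit/extension/truncation variant (~13k deduplicated cases) for
classifier-oracle agreement; a 100,000-read closed-loop sample with a
12-class composition (recovery within 3 binomial SD per class, exact read
conservation); 500 null simulations for Welch and exact-test type-I rates;
20 seeds each for 4× spiked-count recovery (40 miRNAs, depth 50k, 5v5),
ΔΔCt recovery of a −3.33-fold spike (Ct sd 0.3, n = 5/group, success =
p < 0.05 and |FC| within a linear ±30% band), and Spearman/complete
two-group segregation (50 miRNAs with a log-normal base profile, 10
spiked 6×, depth 20k, 3v3). The ΔΔCt recovery simulation contains no
per-sample offsets and no dropout censoring, so it measures the estimator
itself; offset removal and dropout handling are tested separately. With
Ct sd 0.3 and n = 5/group the ΔΔCt standard error is
0.3·√(2/5) ≈ 0.19 cycles, so the per-seed success probability of the
±30% band is ≈ 0.95 — the ≥ 90%-of-20-seeds criterion is expected to
pass but is intrinsically a binomial event, not a certainty.

## Known limitations

* Substring matching (not alignment) for auxiliary databases ignores
  mismatches and can under-call divergent contaminants.
* Dataset-level published counts (per-sample read totals, the 178/146
  detected-set sizes, the full detection grid) depend on the original raw
  data, which is not deposited; the package reproduces the printed-table
  arithmetic and the methodological behaviour, not those dataset-specific
  numbers. The published precursor-dominance figure (">60%") conflates
  mapping ambiguity with true precursor reads and is likewise not a
  reproduction target.
* The two implemented DE tests (welch_log, exact_count) represent the
  limma/DESeq/edgeR comparison by behaviourally equivalent simplified
  tests; claims rest on recovery properties, not package equivalence.
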