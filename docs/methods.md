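# Methods

## The measurement problem

FFPE fixation damages DNA in two ways this package quantifies from aligned
reads. First, formalin introduces interstrand crosslinks preferentially at
adenine residues; during extraction, strands break adjacent to these
crosslinks, so the reference base immediately outside a sequenced molecule's
5' end is enriched for adenine (A-fragmentation; means around 50%, maxima
above 60% against a genomic background of ~29%). Second, hydrolytic cytosine
deamination converts C to U (read as T) preferentially in the
single-stranded, frayed molecule ends: C>T frequencies around 3% at terminal
positions decaying to ~1% in the interior. In double-strand library
preparations the original 3' end of a molecule is frequently replaced by a
copy of the complementary strand, so the same chemistry surfaces as G>A at
read 3' ends; single-strand preparations read the molecule strand itself and
show C>T at both ends.

## Damage profiling

Substitution frequencies are conditional on the reference base per aligned
column: rate(X>Y at position p) = #(ref X, query Y) / #(ref X), computed
from both molecule ends over the first `k_positions` (default 25) columns.
Flanking composition covers `flank` (default 10) reference bases outside
each end. Reads are taken in *molecule* orientation for ss libraries
(reverse-strand reads reverse-complemented together with their reference
context) and *as-mapped* for ds libraries; this default reproduces the
ds-specific A-outside-5'/T-outside-3' and 3'-G>A signatures. Columns with N
in query or reference are excluded from denominators; gapped reads are
excluded entirely (the positional model assumes column-wise alignment) but
still count in mapping statistics. Reads whose flank window leaves the
contig are skipped and counted.

Two interior C>T estimators are reported. `rate_interior` pools positions
10..k from both ends — the conventional read-out, but when end elevation
decays exponentially with scale ~5 bp these columns still carry ~5–15% of
the end excess, so its expectation sits slightly above the true plateau
(~0.011 for the default preset). `rate_interior_deep` pools only columns at
least k positions from *both* molecule ends, where the residual is below
2e-4; recovery tests use it.

Profiling uses a seeded 100,000-read subsample of unique mapped reads with a
30 bp minimum length; length distributions use a 10 bp minimum, and the
median is the standard order statistic.

## Library accounting

`mappable_bp = molecules_total × (reads_unique_mapped / reads_total) ×
median_length` extrapolates the ddPCR molecule count to deliverable unique
sequence; dividing by 3.3e9 bp (genome) or 3.3e7 bp (exome) gives the
anticipated coverage. The two divisors are exposed as configuration; they
were fixed by back-solving the published accounting rows, which they
reproduce within 1%. Fold-enrichment divides the on-target read fraction by
the target's genome share (default 0.01), making capture efficiency
comparable across target designs.

Complexity uses binomial-thinning rarefaction over the duplicate-group-size
multiset: E[unique at depth s] = Σ (1 − (1 − s/N)^cᵢ). This models each read
surviving independently with probability s/N (not without-replacement
subsampling, which differs at toy sizes: for groups {2,1,1} at half depth
the thinning expectation is 1.75, the hypergeometric one 1.83; at real
depths the difference is negligible). Extrapolation beyond observed depth
scales group sizes by the total-molecule/sequenced-molecule ratio and
re-applies the same formula; it is labelled *naive* because no
unseen-species model is fitted, and it answers only the question the
accounting needs (is the library rich enough to keep sequencing), not the
full species-accumulation problem.

Duplicates are keyed on (contig, start, end, strand). Merged single-end
reads observe both physical molecule ends, so this coordinate pair
identifies the source molecule; the first-seen member of each group stays
non-duplicate. A production tool keyed on unmerged pair orientation may
group slightly differently; the key used here is the stated contract rather
than a claimed re-implementation of any particular tool.

Group contrasts use the exact two-sided Wilcoxon rank-sum distribution when
the pooled sample is tie-free, and otherwise the normal approximation with
mid-ranks, tie correction and continuity correction — the fallback
convention of R's `wilcox.test`, which reproduces the published
tie-affected contrast (7.995e-06) exactly. Storage-time trends are ordinary
least squares of each damage metric on years of storage with adjusted R²
and Holm correction across the metric family (the correction method is a
package choice, logged in the output; the source analysis named none).

## Variant QC and the false-positive model

A call passes the filter iff coverage ≥ 8 unique reads AND alt frequency
≥ 10% AND (by default) at least one alt-supporting unique read on each
strand. Rejections are tallied under the first failing rule in that order,
so tallies plus passes sum to the input. Ingestion accepts samtools-style
VCF (per-strand support from DP4) or a flat TSV; positions convert from
1-based at the boundary. Repeat-region masking can be done upstream; it is
not re-implemented here.

Damage-driven false positives are modelled per site as X ~ Poisson(r × c)
damaged reads at damage rate r (default 0.01) and coverage c ≤ 100, calling
a false positive when X ≥ max(2, k(c)). The reporting threshold k(c) is
ambiguous in the convention it models ("5% of reads"): *strict* takes the
smallest integer strictly exceeding 0.05c, *inclusive* the smallest integer
reaching it. Both are implemented behind a flag and both are always
reported; they differ up to an order of magnitude at some coverages (at
c = 100: 5.9e-4 vs 3.7e-3) and their curve maxima are ~5.9% and ~6.2% at
c ≈ 39–40, where the two-read minimum is the binding rule. No single
"percent false positive" number is asserted.

## The simulator: what a green test establishes

The generator emulates the statistical structure the analysis assumes, with
every quantity owned by a closed form:

* Reference: i.i.d. bases at chosen GC (default 0.42, the human genome's
  overall GC), default 1 Mb — large enough that duplicate-key collisions
  between distinct fragments are negligible at 100,000 fragments.
* Lengths: log-normal (median exp(μ), default median 61 bp for ss and 86 bp
  for ds — the observed medians of the two library types; σ = 0.35 chosen
  to keep most molecules under ~100 bp as observed for FFPE DNA), truncated
  at 10 bp.
* Breakpoints: the molecule's 5' breakpoint falls with weight `a_bias` (vs
  1) at positions whose 5'-neighbouring base on the template strand is A.
  The expected flanking-A fraction is w·a/(w·a + 1 − w) for template-A
  fraction w, inverted to hit a target (0.53 for the FFPE presets). Only
  the 5' break is biased; the 3' flank stays at baseline.
* Deamination: each C converts with probability interior + (end −
  interior)·exp(−d/decay), d the distance to the nearer end (decay 5 bp).
  ss reads are the molecule strand itself. ds reads additionally convert G
  with the same rate law measured from the 3' end, modelling the fill-in of
  the 3' region from the complementary strand's deaminated 5'; interior G>A
  equals interior C>T there, matching ds data where reads come from both
  strands.
* Duplication: geometric copy counts (mean `duplication_mean`, default 2),
  the single-parameter law of constant per-cycle amplification efficiency;
  PCR copies replicate the damaged molecule exactly.
* Variants: planted at known sites on both strands of the duplex with a
  per-molecule Bernoulli carrier probability.

Truth SAM records are emitted directly (the mapper is bypassed), so
recovery tests compare against exact truth and no aligner is needed; a FASTQ
writer exists for users who want to exercise a real mapper. All randomness
flows from one seeded numpy Generator, making outputs bit-stable per seed.

What the simulator does **not** model: sequencer error beyond the damage
process, base qualities, paired-end structure before merging, mappability
variation and repeats, intrastrand crosslinks and the tandem substitutions
they cause, G>T adducts, and capture bias (GC preference of hybridization).
A green recovery test therefore establishes that the estimators measure
what they claim on data satisfying the model's assumptions — not that any
particular archival sample shows a particular damage magnitude. Sample-
specific published magnitudes (e.g. a 66% maximum flanking-A, storage-time
R² around 0.3) depend on raw reads that are not public and are deliberately
not asserted anywhere in the test suite.

## Numerical choices

* Frequencies divide by per-position reference-base counts; empty
  denominators yield 0 rather than NaN.
* Composition rows renormalise over {A,C,G,T} after excluding N.
* Reservoir sampling (Algorithm R) with an explicit seed gives deterministic
  subsamples that preserve stream order.
* Ratios in table-style CLI output are rounded half away from zero to
  integers, mirroring the convention of the published yield table; raw
  fractions are always written alongside.
* Rarefaction grids step by 100,000 reads (configurable) and always include
  the observed endpoint, where the curve equals the observed unique count
  identically.
* `estimate_mappable_bp` multiplies the unique fraction and mapped-of-unique
  fraction as the single ratio unique_mapped/total, avoiding intermediate
  rounding.

## Known limitations

* The duplicate key cannot separate distinct molecules that happen to share
  both endpoints and strand; at FFPE-typical depths and genome sizes this
  is negligible, on tiny toy references it is not.
* The naive complexity extrapolation understates the unique yield of
  libraries whose group-size law is heavier-tailed than the observed
  sample.
* The exact Wilcoxon path requires a tie-free pooled sample; with ties the
  reported p is approximate (flagged `tie_corrected`).
* The false-positive model treats sites independently and ignores strand
  asymmetry of damage within a site; it brackets, rather than pins down,
  the expected false-positive fraction.
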