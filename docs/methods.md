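# Methods

## Scope and data model

`meripkit` analyses MeRIP-seq experiments reduced to read intervals
(BED) plus transcript models (GTF) and sequence (FASTA). All
coordinates are 0-based half-open internally; GTF is converted on read.
Interval intersection, merging (book-ended intervals join at gap 0) and
≥1 bp overlap counting are implemented on sorted arrays and are checked
against per-base brute-force oracles in the test suite. Peak calls are
treated as unstranded genomic features; transcript anatomy (TSS, UTRs,
CDS, spliced coordinates) is always strand-aware. A peak overlapping
several transcripts is attributed to the longest coding transcript
(transcript id as tie-break) — the attribution rule for multi-gene loci
is genuinely open, and this deterministic choice is exposed through
`TranscriptIndex.assign`.

## Built-in peak caller

The built-in caller is a stand-in for external callers, whose BED
output can be imported instead: it slides a window (default 100 nt,
step 50) and computes the exact Poisson upper tail of the IP read count
against an expectation derived from the input. The expectation is
estimated from the input reads in a wide local background (window ±
2,500 nt, clipped to the chromosome), rescaled by read-capture length
and the IP/input library-size ratio and floored at one read. Using a
wide background keeps input-count noise from inflating the test's size
(a window-sized input estimate roughly doubles the variance of the
IP−expectation difference and is visibly anti-conservative in the null
simulation), while still tracking per-transcript expression; near
chromosome edges the clipped estimate is conservative. Significant
windows (default p < 1e-6, matching the stringency commonly applied to
external callers) are merged into peaks. Summits are located afterwards
at the maximum of pooled IP minus library-scaled pooled input coverage
(leftmost base on ties).

Two-caller consensus is base-wise intersection followed by merging.
"Detected in at least `min_support` samples" (default 2) is evaluated
on the merged candidate regions with ≥1 bp overlap counting as
detection; the overlap rule is a convention choice, not dictated by the
recipe. The m6Am filter removes 5'UTR-assigned peaks whose interval
covers the TSS of their transcript when the first transcribed base is A
or the TSS-centered −1..+1 trinucleotide (transcript orientation)
matches B-C-A with IUPAC B = {C,G,T}; whether TSS coverage should be
required is ambiguous, so `require_tss_cover=False` switches to
filtering any A/BCA-start 5'UTR peak.

## Quantification and differential calls

Counting is read-level: a read contributes to every peak it overlaps by
≥1 bp (a base-coverage alternative was considered and rejected to keep
counts integral for the Poisson machinery; the ambiguity is noted
here). Library size is the library's total read count, per the RPKM
definition, not reads-in-peaks. Enrichment is IP RPKM over input RPKM
with pseudocount 0 by default; cells with zero input RPKM are masked
(NaN) rather than imputed, and a pseudocount (e.g. 0.5 RPKM) is
available for shallow data. Per-pair fold changes, the ≥1.5-fold /
≥4-of-8-pairs classification, the increased/decreased percentage split
(rounded half-up to two decimals), and the global tumor-vs-normal shift
histogram (difference and log-ratio modes, since the transform of the
published histogram axis is not stated) follow directly. `min_pairs` is
an absolute count even when some pairs are masked; peaks with fewer
valid pairs than `min_pairs` are reported as `undefined`, and peaks
satisfying both arms as `ambiguous`, outside the dysregulated
denominator.

## Annotation

Region assignment uses the peak summit. Start/stop-codon windows are
±100 nt in spliced coordinates (the region width is not standardized;
100 nt matches fragment-scale resolution) and take precedence over the
plain 5'UTR/CDS/3'UTR labels. Metagene profiles rescale each region to
fixed bin counts (default 20/50/30) and normalize to unit mass. Motif
scanning expands IUPAC codes to character classes with overlapping
matches; minus-strand hits are reported in plus-strand coordinates.
Motif enrichment compares observed match density with
dinucleotide-preserving shuffles (Altschul–Erickson edge shuffling,
implemented here because no installed library provides it) and reports
the add-one empirical p-value. Reference-catalogue comparison counts
peaks containing ≥1 recorded site and reports a half-up-rounded
percentage.

## Co-occupancy and gene sets

`aggregate_profile` reports mean per-base interval coverage per offset
bin around anchor positions (strand-aware axis flip), so wide CLIP
clusters contribute proportionally to their footprint — the natural
reading of an "intensity" axis. The permutation test re-places site
midpoints uniformly over a stated domain and uses the add-one empirical
tail. Gene-set over-representation uses the exact hypergeometric upper
tail with a detectability-conditioned universe (genes carrying a tested
peak) and BH correction; GMT files are the exchange format.

## Synthetic data generator

The generator emulates the profiled study design: 8 tumor/normal pairs
(16 samples, IP+input each), 300 single-exon transcripts (5'UTR ≈ 180
nt, CDS ≈ 750 nt, 3'UTR ≈ 350 nt; lognormal expression, σ = 0.5), and
100 m6A sites planted on exact GGACT occurrences with region weights
0.1/0.3/0.6 for 5'UTR / CDS body / stop-proximal, reproducing the
stop-codon concentration of real m6A. 30% of sites are differential
(tumor fold 3); 7.5% of the differential sites decrease rather than
increase, mirroring the reported two-direction split of dysregulated
peaks. Input read counts per transcript are negative binomial
(Poisson-gamma, size 100 ≈ 10% extra-Poisson CV, technical-replicate
scale; size → ∞ recovers Poisson for closed-form checks) with uniform
read starts; IP reads are drawn with a multiplicative boost (baseline
enrichment 4) for fragments overlapping ±100 nt of a site,
approximating fragment-level MeRIP resolution. Depth defaults to ~100
expected input reads per site window. One master seed is split into
truth / per-library / CLIP streams via `SeedSequence.spawn`, so runs
are byte-reproducible and adding samples never perturbs earlier ones.
RBP sites are intervals centered on a configurable fraction of m6A
sites with Gaussian jitter, plus uniform background intervals.

Because enrichment divides by the realized IP library size, a
sample-wide methylation gain slightly deflates every ratio in that
sample (with the defaults, tumor ratios are attenuated by ~15–20% and
null peaks drift a few percent below 1). This is a property of the
RPKM-ratio estimator itself, not of the generator; the defaults keep
planted windows a small share of library mass so the classification
margins dominate it. The calibration claims (non-site ratio ≈ 1, site
ratio ≈ planted enrichment, pair fold change ≈ configured fold) are
exact in the sparse-site regime and are tested there.

What the generator does not model: sequencing error, mappability,
fragment-length variation (reads have fixed length), GC effects,
isoform mixtures, and biological replicate dispersion beyond the NB
size. Passing recovery tests therefore demonstrates the pipeline logic
under calibrated noise, not robustness to alignment artifacts or
between-patient heterogeneity. The optional multi-exon mode exercises
spliced-coordinate logic; junction-spanning fragments are emitted as
per-exon blocks and counted once per block, so quantification tests use
the single-exon default.

## Problem sizes and numerical choices

Default analyses run in seconds: the recovery checks use three seeds of
the full default design (~0.4M reads per sample pair); oracle suites
use ≤1 kb spans and ≤20-gene universes where exhaustive enumeration is
exact. Poisson tails are exact (`scipy.stats.poisson.sf`), verified
against 50-digit summation to 1e-12; hypergeometric tails against
rational-arithmetic draw counting. Percentages are rounded half away
from zero to two decimals for report parity. Degenerate inputs are
rejected early: empty or inverted intervals, zero library sizes,
zero-depth designs with planted sites, `min_pairs` exceeding the number
of pairs, and unknown configuration keys.

## Clinical scoring helpers

The immunoreactive score multiplies staining intensity (0–3) by the
positive-cell extent grade (1: ≤25%, 2: 26–50%, 3: 51–75%, 4: >75%;
band edges closed as stated). Xenograft volume is length × width² × 0.5
(mm³); swapped axes are corrected with a warning rather than rejected,
since the longer axis is the length by definition.
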