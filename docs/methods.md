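# Methods

This note documents the statistical models, the numerical conventions and
the deliberate design choices in `ribodelta`, in the order the pipeline
runs them. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Transcript models and ORF segmentation

Transcripts are assembled from exon records into a spliced coordinate
system (0-based, half-open; GTF I/O converts from 1-based closed at the
boundary). Position 0 is always the 5' end: minus-strand exons are ordered
by descending genomic coordinate and reverse-complemented individually.

UTR/CDS boundaries are derived from sequence, not from annotated CDS
features, so the segmentation works on assembled transcripts: the CDS is
the longest ATG-initiated open reading frame over all three forward
frames. Conventions where the procedure is otherwise underdetermined:

* **Ties** (equal length): the 5'-most start wins. Deterministic output.
* **No in-frame stop**: the ORF is accepted and truncated at the last
  complete codon. Assembled transcripts are frequently 3'-incomplete, and
  rejecting them would silently bias region analyses toward well-annotated
  genes.
* **N bases** never match ATG or a stop codon (conservative).
* Transcripts with no ORF are excluded from region-level analyses but kept
  in whole-transcript binning, where no segmentation is needed.

The implementation is checked against a brute-force enumerator of every
(ATG, first in-frame stop) pair on random sequences.

## Positional coverage profiles

Per-nucleotide depth is accumulated by projecting genomic alignment blocks
(CIGAR N respected) onto spliced coordinates; bedGraph depth is projected
the same way. Transcripts enter the positional analysis if mean depth ≥ 1
read/nt (inclusive boundary).

The 100-bin profile uses the floor rule — bin *b* covers spliced positions
[⌊bL/100⌋, ⌊(b+1)L/100⌋) — which is total-preserving for any L; bins made
empty by L < 100 receive fraction 0. Fractions are per-base depth sums over
total depth, so profiles sum to 1 exactly and are invariant to uniform
depth scaling.

Aggregation treats **animals as the replication unit**: within each animal
the per-bin median across transcripts, then across animals of a genotype
the mean and SEM of those medians. A genotype with one animal is flagged
(SEM undefined) rather than silently dropped. Any N ≥ 2 animals per
genotype is accepted.

Region statistics use the same depth split by the segmentation. Per
transcript, the genotype difference of mean region read-fractions
(mutant − control) feeds a one-way ANOVA across the three region groups
with Tukey HSD pairwise comparisons (statsmodels).

**3'UTR-biased selection.** Among DE-downregulated transcripts, a
transcript is selected when its 3'UTR change is *strictly* more negative
than its overall log2 fold change. The 3'UTR change is computed as the
genotype difference of mean log₂(mean 3'UTR depth + 1), which puts the
region change on the same log2 scale as the transcript-level fold change;
this scale choice is a documented substitute for an unspecified criterion,
not a claim of uniqueness.

## Differential expression

One engine serves both the RNA and the TRAP matrix: per gene a two-group
comparison of log₂(x+1) values after counts-per-million scaling (scaling is
on by default because raw counts confound fold change with sequencing
depth; it can be disabled for exact-arithmetic checks).

Variance moderation follows the standard empirical-Bayes scheme: gene-wise
pooled variances s²_g (d = n₁+n₂−2 df) are shrunk toward a prior,
s̃² = (d₀s₀² + d s²)/(d₀+d), with (d₀, s0²) estimated by the method of
moments on log s² using the exact digamma/trigamma moments of log χ²
(trigamma inverted by Newton iteration). If the observed spread of log s²
does not exceed the sampling spread, the prior is degenerate (d₀ = ∞) and
all genes share the pooled mean variance. The moderated t is referred to a
t distribution with d+d₀ df. Setting d₀ = 0 recovers the ordinary
two-sample t exactly, which the tests exploit.

Significance is the raw-p rule: |log2FC| > log₂(2) **and** p < 0.01, both
strict (a gene at exactly the boundary is not significant). A BH-FDR
column is emitted for diagnostics but never drives the flags.

## ΔTE and the jackknife Z-score

ΔTE per gene is the difference of differences of group means of
log₂(CPM+1), over four groups (RNA × genotype, TRAP × genotype). The
default design has 4/4 RNA and 3/3 TRAP samples.

**Resampling scheme.** "Leave one value out of each dataset" is read as
simultaneous single deletions in all four groups; the full Cartesian
product (144 combinations for 4/4/3/3) is subsampled, seeded and without
replacement, to at most 100 combinations per gene. An exhaustive
enumerator is kept in the test suite as the oracle.

**Scaling.** The raw spread of simultaneous leave-one-out values has
expected variance Σ_g σ²_g/(n_g(n_g−1)), whereas the ΔTE estimator's
variance is Σ_g σ²_g/n_g. The reported `jackknife_sd` is therefore the
sample sd of the resampled values times

    c = sqrt( (Σ 1/n_g) / (Σ 1/(n_g(n_g−1))) )

the exact correction under a common within-group variance — this is the
usual jackknife rescaling generalized to several groups. c = 1 when every
group has two samples, and c ≈ 1.53 for the 4/4/3/3 design. Without this
factor the Z-scores would be inflated ~1.5-fold. With heteroscedastic
groups the correction is approximate (the weighting across groups is then
slightly off, bounded by the spread of σ²_g).

**Degenerate spreads** are flagged, never floored: sd = 0 with ΔTE = 0
gives z = 0; sd = 0 with ΔTE ≠ 0 reports z as missing with an `unstable`
flag. A silent variance floor would hide exactly the pathological genes one
needs to see.

Z is thresholded strictly at |Z| > 4; the one-sided upper tail of the
standard normal at 4 is 3.167·10⁻⁵. One-sided p is the primary output
(matching the pairing of "greater than 4" with that tail), two-sided p is
a column. Gene-set shifts in ΔTE use Welch's t (set vs complement) with
ECDF exports for plotting.

**Known limitation — small-sample calibration.** With 14 samples total,
each gene's sd estimate carries roughly 9 effective degrees of freedom, so
under the null z behaves like a t₉ variate, not a standard normal: the
|z| > 2 tail mass is ≈ 7–8.5% rather than 4.6% (the acceptance script
measures it). No per-gene resampling scheme can fix this — it would
require cross-gene variance moderation, which this stage deliberately does
not apply, to keep the statistic faithful to the jackknife-Z design.
Consequences at |Z| > 4 are milder but real: the threshold is
anti-conservative relative to its nominal normal tail.

## Enrichment

Overlap significance is the exact hypergeometric upper tail P(X ≥ k)
(scipy), validated against full combinatorial enumeration for all N ≤ 25.
The **universe** is the set of genes passing the expression filter in the
relevant matrix, not the whole annotation — never-observed genes would
otherwise inflate every enrichment. Enrichment is always the upper tail;
depletion is out of scope. Expression-matched control sets use 10 quantile
bins over the target genes' expressions, drawing per bin exactly as many
pool genes as there are targets (seeded, without replacement); a bin the
pool cannot fill is an error naming the deficient bins, never a silent
fallback. Mann–Whitney comparisons use exact enumeration for combined
n ≤ 12 without ties and the tie-corrected normal approximation otherwise.

## The synthetic-data generator

The generator's defaults are the emulated study conditions: 2,000 genes,
4v4 RNA and 3v3 TRAP samples, negative-binomial counts with gene-shared
dispersion 0.1, baseline means log-normal with median 50 (a depth at which
every stage runs in minutes on one CPU), and planted groups

| group | RNA log2FC | TRAP log2FC | true ΔTE | default share |
|---|---|---|---|---|
| fmrp_like | −1 | 0 | +1 | 8% |
| top_like | 0 | +0.5 | +0.5 | 5% |
| down_both | −1 | −1 | 0 | 4% |
| null | 0 | 0 | 0 | 83% |

The shares are scaled from the relative sizes of the affected gene lists
in the emulated study (~1,000 of ~12k expressed genes in each signature
class). Transcript architecture: ATG-free 5'UTR of 50–300 nt, planted CDS
of 200–600 codons (long enough that spurious ORFs longer than the planted
one are vanishingly rare), 3'UTR of 100–400 nt, 1–4 exons on either
strand, each transcript on its own synthetic chromosome.

Coverage decay acts on **reads, not depth**: read 5' starts are uniform
and each read survives with probability (1 − decay)^(d/100), d the
distance of its 3'-most base from the transcript 5' end, so coverage stays
integer and read-level statistics remain meaningful. Mutant samples apply
the decay (by default to RNA-downregulated transcripts); control samples
never do.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: GC/mappability bias, fragment-length and
positional library-prep artifacts, isoform mixtures, correlated
gene-gene noise, batch structure, and count–coverage coupling (counts and
per-base coverage are drawn independently given the group labels). Results
on real data additionally depend on upstream alignment quality, which this
package consumes as given.

## Determinism and numerics

Every random stream is a pure function of (seed, stage name); the pipeline
derives per-stage seeds from a single master seed, so `run-all` equals the
composition of the standalone subcommands byte-for-byte and rerunning with
the same seed reproduces identical checksums (recorded in the manifest).
Numeric tables are written with 17 significant digits; all test
comparisons use explicit tolerances. Degenerate inputs (zero-depth
profiles, empty sequences, single-animal genotypes, zero-variance
correlations) raise typed errors or set documented flags rather than
returning silent NaNs.
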