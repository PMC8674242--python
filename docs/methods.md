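# Methods

## Model

A called somatic mutation is treated as a hypothesis to be tested
against the read-level evidence at its locus. The null alternative is
that the mutation arose as a microhomology-induced chimeric read during
library end repair, via one of two mechanisms: fold-back on a proximal
palindrome (hairpin) or mis-annealing of single strands from distant,
locally identical regions. Both mechanisms leave three observable marks
on the supporting reads: the mutated base sits near one effective read
end (the chimeric remainder is soft-clipped), the sequence around the
mutation matches the opposite strand nearby, or it matches another
genomic region exactly.

### Supporting lengths

For each read, the 5′ (resp. 3′) supporting length is the number of read
bases from the base adjacent to the mutated bases to the furthest mapped
base on that side, in reference orientation. Soft- and hard-clipped
bases count toward neither side; read bases consumed by insertions
elsewhere in the alignment do count (read-base counting); deletions
consume none. The shorter supporting length is the minimum of the two.
The mutated bases themselves are excluded, so for a clip-free read of
post-trim length L supporting an N-base substitution, len5 + len3 + N = L.

### Theoretical bounds

For an N-base substitution the directional supporting lengths can take
any value in [0, L−N] (a mismatched base maps like any other). For
indels two constraints apply: a supporting read must contain the entire
repeat run flanking the event (a read ending inside the run is gaplessly
consistent with the reference and cannot evidence the indel), and each
flank needs at least N+1 anchor bases, because keeping an N-base gap
scores m − (N+6) against the flat soft-clip penalty of 5 under the
aligner's model, so the gap survives only when m ≥ N+1. Hence each
directional minimum is max(R, N+1), with R the tandem-repeat run length
on that side (R5′ on the 5′ side, R3′ on the 3′ side; the unit is the
inserted/deleted sequence, extended base-by-base including a trailing
partial copy). Maxima follow from geometry: L − max(R, N+1) for
deletions, L − N − max(R, N+1) for insertions. Shorter-length bounds
are the floor-halved analogues: max ⌊(L−N)/2⌋ for substitutions and
insertions, ⌊L/2⌋ for deletions (which occupy no read bases); the
shorter minimum is the smaller of the two directional minima.

These closed forms are checked in the test suite against an exhaustive
placement oracle that enumerates every read position over a constructed
mutated template and applies the two per-read rules by direct string
comparison. A fully realignment-aware aligner model can disagree with
the closed forms in repeat contexts (a read barely covering the run can
still be explained without the gap at equal score); the closed forms are
the committed model and the oracle embodies its two stated rules.

### The positional-bias test (Filters 1 and 3)

Let [A, B] be the observed supporting-length band over the E
mutation-supporting reads (values clamped into [C, D]; excursions are
logged, not fatal), and f the empirical distribution of the same
statistic over the non-mutant reads at the locus. Then

p = ( Σ_{m=A..B} f(m) / Σ_{n=C..D} f(n) )^E,

computed as a direct power when safe and in log space otherwise (the two
agree to 10⁻¹² relative error; verified against exact rational
arithmetic). Filter 1 uses the shorter supporting length; Filter 3
applies the same test to the 5′ and 3′ lengths separately and trips if
either does. A mutation is flagged when p < 10⁻⁶ (strict), chosen over
10⁻⁵ to avoid over-filtering.

Exemptions (the test is withheld): observed band wider than 75% of the
theoretical band; observed band carrying more than 75% of the null mass
(both strict, evaluated on integer counts); no usable null reads. If
any supporting read has more than three mismatches within the ten
reference bases surrounding the mutation (five per side, mutated bases
excluded, counted on aligned bases only), clustered mutations inflate
the anchor requirement, so the theoretical minimum is set to 0 for all
three statistics before testing.

When f has no mass on [C, D] the test falls back to a uniform null over
[C, D] and logs it. A variant null built from the mutant reads
themselves is available behind `PipelineConfig.null_from_mutant_reads`
for comparison; the default is the non-mutant null.

### Hairpin detection (Filter 2)

From each supporting read, a window of max(15, N+14) read bases centered
on the event (7 per flank; for deletions, which occupy no read bases,
7 left and 8 right of the junction) — including soft-clipped bases,
which is where the chimeric copy lives. The read is hairpin-derived iff
the window's reverse complement occurs exactly in the reference within
±200 bases of the locus (200 because widening the search range beyond it
yields no additional palindromes in practice, while 150 misses some).
Reads too short for the window count as non-hairpin. Flag when the
hairpin-read rate strictly exceeds 50%.

### Distant-homology detection (Filter 4)

Per supporting read, a core of the event bases plus the read bases
covering the flanking repeat runs is extended to two 40-mers: four read
bases prepended 5′ and filled 3′-ward, and the mirror image. A read
matches when either 40-mer occurs exactly, on either strand, outside an
exclusion zone of ±200 bases around the locus (preventing trivial
self-matches; the proximal palindrome case belongs to Filter 2). All
queries in a batch are matched in a single linear pass per contig
against a hash set, so runtime is O(genome) regardless of mutation
count; correctness is defined by equivalence with a naive scan and
tested as such. Flag when more than 15% (strict) of supporting reads
match, with all supporting reads as the denominator (reads yielding no
valid query count as non-matching — conservative against
over-filtering).

### Combination

Verdict = artifact iff any of Filters 1–4 trips. Filters annotate and
never drop rows; a mutation with no supporting reads passes with an
`insufficient_reads` exemption; one mutation's failure never aborts a
batch. Loci with depth below 100 get a warning because the
positional-bias test loses power there.

## Input handling

Mutation lists are TSV (Sample/Chr/Pos/Ref/Alt), 1-based, accepting both
anchored indel alleles and the "-" dialect (anchor read from the
reference). Internally everything is 0-based half-open. Reads are
fetched per locus from an indexed BAM; secondary, supplementary and
duplicate-flagged alignments are excluded, MAPQ-0 reads retained, and
both mates of an overlapping pair count as two observations. The 3′
sequencing adapter is trimmed (suffix alignment, ≤ 10% mismatches,
iterated to a fixpoint so trimming is idempotent) before any length is
measured — a no-op on pre-trimmed libraries. Reads whose alignment
places the locus inside a soft clip join neither the supporting nor the
null set. Read length L for the bounds is the maximum post-trim read
length among the reads used at the locus; lengths enter the statistics
per read.

## Synthetic data

The generator emulates the read-level *signatures* of the two chimera
mechanisms, not library chemistry. Defaults: 200 kb two-contig random
genome, 50 sites per class, 150-base reads, depth 200, VAF 0.25 (so the
non-mutant background is ~3× the mutant depth and populates the null
well), constant-high base qualities. Hairpin sites get a planted
reverse-complement arm 40–180 bases downstream and artifact reads with
the alternate base pinned 7–10 bases from the mapped 3′ end, the rest
soft-clipped; homology sites get a distant (other contig or > 10 kb)
60-base copy differing only at the mutated base, and artifact reads
whose mutation offset keeps the 5′-anchored 40-mer inside the copy;
true sites sit on sequence verified unique by self-scan, with uniform
fragment starts. All outputs are a deterministic function of
(spec, seed).

What passing tests on this data do show: each filter responds to
exactly the evidence pattern its mechanism produces, thresholds behave
strictly at their boundaries, and true mutations with uniform support
are never flagged. What they do not show: performance on real FFPE
libraries, whose fragment-size distributions, quality decay, deaminated
cytosines and mixed artifact modes the generator does not model; only
SNV sites are planted (indel paths are exercised by unit tests with
hand-built alignments).

## Numerical and design choices

* Probability threshold comparisons are strict (<); rate thresholds are
  strict (>); the 75% exemptions are strict (>) on integer counts, so
  boundary cases are exact.
* Observed supporting lengths outside [C, D] are clamped and logged.
* p is computed as a direct float power unless the exponent would
  underflow (E·log(ratio) < −700), then in log space.
* Problem sizes in the acceptance script (genome 300 kb for search
  oracles, depth sweep at 25 loci per depth) were chosen as the
  smallest sizes at which the statistical assertions are stable across
  seeds.

## Known limitations

* Supporting-length orientation is referential, not sequencing-strand;
  directional (Filter 3) results could differ under the other
  convention, the shorter length (Filter 1) cannot.
* The repeat-run definition is tandem extension of the indel unit;
  other microsatellite definitions would shift bounds in exotic
  contexts.
* No mate-collapsing, no realignment/left-normalization of input BAMs,
  no CRAM, no approximate homology search (exact 40-mer identity only,
  by design).
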