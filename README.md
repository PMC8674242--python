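# microsec

Post-hoc filtering of chimeric-read artifacts in somatic mutation calls
from FFPE (formalin-fixed, paraffin-embedded) sequencing data.

## The problem

DNA from FFPE tissue is fragmented and partly single-stranded. During the
end-repair step of library preparation, a single-stranded fragment can

* fold back on a nearby palindromic sequence (a hairpin), or
* mis-anneal with a fragment from a distant but locally identical region,

after which the polymerase copies the one mismatched base between the two
sequences into the library. The result is a *microhomology-induced
chimeric read*: a read that looks like it supports a somatic mutation but
is a library-preparation artifact. These artifacts pass ordinary
caller-level filters because they are real bases on real reads. Their
read-level signature, however, is distinctive: the false mutation sits
close to one effective end of every supporting read (the rest of the read
is soft-clipped), and the sequence around it exists on the opposite
strand nearby or verbatim elsewhere in the genome.

`microsec` takes a list of called mutations, the corresponding BAM and
the reference FASTA, and annotates each mutation with four filters:

| Filter | Evidence |
|---|---|
| 1 | supporting lengths (shorter of 5′/3′) occupy an improbably narrow band |
| 2 | > 50% of supporting reads have a 15-mer around the mutation whose reverse complement occurs within 200 bases |
| 3 | same as 1, applied to the 5′ and 3′ supporting lengths separately |
| 4 | > 15% of supporting reads carry a mutation-containing 40-mer that occurs exactly elsewhere in the genome |

A mutation is called an **artifact** when any filter trips.

The positional-bias statistic (Filters 1, 3) compares the observed band
[A, B] of supporting lengths over the E mutation-supporting reads with
the band [C, D] the aligner could theoretically produce, using the
empirical distribution *f* of supporting lengths among the non-mutant
reads at the same locus:

```
p = ( Σ_{m=A..B} f(m) / Σ_{n=C..D} f(n) )^E
```

Mutations with p < 10⁻⁶ are flagged, unless the observed band covers
more than 75% of the theoretical band in width or in null mass (deep
sequencing drives p to zero for perfectly ordinary spreads), in which
case the test is withheld. For an N-base substitution in reads of length
L the theoretical band is [0, L−N]; indel-supporting reads must contain
the full flanking repeat runs R5′/R3′ and at least N+1 anchor bases
(keeping an N-base gap costs N+6 against a flat soft-clip penalty of 5),
flooring each side at max(R, N+1).

## Worked example

The package ships a generator that plants true mutations, hairpin
artifacts and homology artifacts (with truth labels) on a toy genome:

```
$ microsec simulate --out-dir demo --seed 5 --n-true 3 --n-hairpin 3 \
      --n-homology 3 --genome-length 60000 --depth 120
$ microsec run --mutations demo/mutations.tsv --bam demo/reads.bam \
      --reference demo/reference.fa --out demo/results.tsv
total	9
removed_by_filter_1	3
removed_by_filter_2	3
removed_by_filter_3	3
removed_by_filter_4	3
removed_by_any_filter	6
passing	3
```

All 6 planted artifacts are flagged (the 3 hairpin sites by Filters
1/2/3, the 3 homology sites by Filter 4) and the 3 true mutations pass.
The results TSV keeps one row per input mutation with the per-filter
evidence, e.g. for a passing true mutation:

```
Sample  Chr   Pos    Ref  Alt  Type  ReadDepth  MutSupportingReads  P_shorter     ...  Exemptions               Verdict
sim     chr2  26663  G    A    SNV   120        28                  3.987757e-02  ...  mass_75pct,range_75pct   pass
```

The `Exemptions` column records why the positional-bias test was
withheld here: the 28 supporting reads spread across most of the
theoretical band, exactly what a true mutation looks like.

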