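"""Synthetic toy genomes and aligned read sets with planted truth labels.

Every filter, and the end-to-end pipeline, must be testable without any
external data.  This module builds a random reference genome carrying
three kinds of planted mutation sites and emits coordinate-sorted
aligned reads (BAM), a mutation list (TSV) and a truth table (TSV):

* **true mutations** — placed on sequence verified unique by self-scan;
  supporting reads have uniform fragment starts, so mutated-base offsets
  are uniform across reads;
* **hairpin artifacts** — the reference carries, within 200 bases of the
  locus, the reverse complement of the mutated local 15-mer (the second
  palindrome arm); artifact reads show the alternate base pinned a few
  bases from their mapped 3' end with the remainder soft-clipped —
  the read-level signature of a fold-back chimera;
* **homology artifacts** — the reference carries a distant (other
  contig or >10 kb away) copy of a 60-base block around the locus
  differing only at the mutated base; artifact reads match that distant
  copy verbatim around the mutation.

Artifacts are planted at the signature level (constrained supporting
lengths, soft-clip CIGARs, verbatim homologous 40-mers) rather than by
simulating library chemistry: the filters see exactly the read-level
evidence the mechanisms produce, which is what tests must exercise.
All outputs are a deterministic function of (spec, seed).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from .read_evidence import revcomp

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic data set.

    Defaults give 150 SNV sites (50 per class) at depth 200 and VAF
    0.25 on a 200 kb two-contig genome with 150-base reads, so the
    non-mutant background at each locus (~3x the mutant depth) populates
    the null distribution well.
    """

    genome_length: int = 200_000
    n_contigs: int = 2
    n_true: int = 50
    n_hairpin: int = 50
    n_homology: int = 50
    read_length: int = 150
    depth: int = 200
    vaf: float = 0.25
    palindrome_arm: int = 20
    homology_block: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0 < self.vaf <= 1:
            raise ValueError("vaf must be in (0, 1]")
        if self.palindrome_arm < 15:
            raise ValueError("palindrome_arm must be >= 15 (hairpin query length)")
        if self.homology_block < 40:
            raise ValueError("homology_block must be >= 40 (homology query length)")


@dataclass
class Site:
    label: str            # true_mutation | hairpin_artifact | homology_artifact
    contig: str
    pos: int              # 1-based
    ref: str
    alt: str
    extra: dict = field(default_factory=dict)


_SITE_SPACING = 700   # between planted loci; keeps filters independent
_EDGE_MARGIN = 600    # from contig ends; reads never run off


def _rand_genome(rng: np.random.Generator, spec: FixtureSpec) -> dict[str, str]:
    per = spec.genome_length // spec.n_contigs
    return {
        f"chr{i + 1}": "".join(_BASES[rng.integers(0, 4, per)])
        for i in range(spec.n_contigs)
    }


def _alt_base(rng: np.random.Generator, ref: str) -> str:
    choices = [b for b in "ACGT" if b != ref]
    return choices[int(rng.integers(0, 3))]


def make_reference(spec: FixtureSpec) -> tuple[dict[str, str], list[Site]]:
    """Random genome plus the site registry.

    Raises when the genome is too small to host the requested sites.
    Hairpin sites receive a planted reverse-complement arm within 200
    bases; homology sites receive a distant near-identical block; true
    sites are verified unique by scanning the finished genome for every
    mutation-covering 40-mer.
    """
    rng = np.random.default_rng(spec.seed)
    genome = {c: list(s) for c, s in _rand_genome(rng, spec).items()}
    contigs = sorted(genome)
    per = len(genome[contigs[0]])

    n_sites = spec.n_true + spec.n_hairpin + spec.n_homology
    # homology sites consume a second, distant slot for the planted copy
    n_slots = n_sites + spec.n_homology
    usable = spec.n_contigs * max(0, per - 2 * _EDGE_MARGIN)
    if n_slots * _SITE_SPACING > usable:
        raise ValueError(
            f"genome too small for {n_sites} sites; need at least "
            f"{n_slots * _SITE_SPACING + 2 * _EDGE_MARGIN * spec.n_contigs} bases")

    slots: list[tuple[str, int]] = []
    for c in contigs:
        p = _EDGE_MARGIN
        while p + _SITE_SPACING <= per - _EDGE_MARGIN:
            slots.append((c, p + int(rng.integers(0, _SITE_SPACING // 2))))
            p += _SITE_SPACING
    order = rng.permutation(len(slots))
    slots = [slots[i] for i in order]

    sites: list[Site] = []
    cursor = 0

    def next_slot() -> tuple[str, int]:
        nonlocal cursor
        s = slots[cursor]
        cursor += 1
        return s

    for _ in range(spec.n_true):
        contig, p0 = next_slot()
        ref = genome[contig][p0]
        sites.append(Site("true_mutation", contig, p0 + 1, ref,
                          _alt_base(rng, ref)))

    for _ in range(spec.n_hairpin):
        contig, p0 = next_slot()
        ref = genome[contig][p0]
        alt = _alt_base(rng, ref)
        # second palindrome arm: revcomp of the mutated local 15-mer,
        # planted 40..180 bases downstream (within the 200-base window)
        local = genome[contig][p0 - 7:p0] + [alt] + genome[contig][p0 + 1:p0 + 8]
        arm = revcomp("".join(local))
        offset = 40 + int(rng.integers(0, 141))
        genome[contig][p0 + offset:p0 + offset + 15] = list(arm)
        s_pin = 7 + int(rng.integers(0, 4))  # pinned 3' supporting length
        sites.append(Site("hairpin_artifact", contig, p0 + 1, ref, alt,
                          {"arm_offset": offset, "s_pin": s_pin}))

    def next_distant_slot(contig: str, p0: int) -> tuple[str, int]:
        # the planted copy must sit on another contig or >10 kb away
        nonlocal cursor
        for j in range(cursor, len(slots)):
            c, p = slots[j]
            if c != contig or abs(p - p0) > 10_000:
                slots[cursor], slots[j] = slots[j], slots[cursor]
                return next_slot()
        raise ValueError("genome too small to place a distant homologous copy")

    half = spec.homology_block // 2
    for _ in range(spec.n_homology):
        contig, p0 = next_slot()
        dcontig, d0 = next_distant_slot(contig, p0)
        ref = genome[contig][p0]
        alt = _alt_base(rng, ref)
        block = genome[contig][p0 - half + 10:p0 + half + 10]
        block[half - 10] = alt      # mutated base inside the copy
        genome[dcontig][d0:d0 + len(block)] = block
        sites.append(Site("homology_artifact", contig, p0 + 1, ref, alt,
                          {"copy_contig": dcontig, "copy_pos": d0,
                           "block_start": p0 - half + 10}))

    out = {c: "".join(s) for c, s in genome.items()}
    _verify_true_sites_unique(out, sites)
    return out, sites


def _verify_true_sites_unique(genome: dict[str, str], sites: list[Site]) -> None:
    """Self-scan: every 40-mer covering a true-mutation site must occur
    exactly once genome-wide (either strand)."""
    queries = {}
    for s in sites:
        if s.label != "true_mutation":
            continue
        p0 = s.pos - 1
        seq = genome[s.contig]
        for start in (p0 - 39, p0 - 20, p0):
            q = seq[start:start + 40]
            if len(q) == 40:
                queries[q] = s
    text = "#".join(genome[c] for c in sorted(genome))
    for q, s in queries.items():
        n = text.count(q) + text.count(revcomp(q))
        if n != 1:
            raise AssertionError(
                f"true-mutation site {s.contig}:{s.pos} is not unique "
                f"({n} occurrences of a covering 40-mer)")


@dataclass
class SimRead:
    name: str
    contig: str
    ref_start: int
    seq: str
    cigar: str
    is_reverse: bool


def _reads_for_site(rng: np.random.Generator, genome: dict[str, str],
                    site: Site, spec: FixtureSpec) -> list[SimRead]:
    L = spec.read_length
    seq = genome[site.contig]
    p0 = site.pos - 1
    reads: list[SimRead] = []
    is_mut = rng.random(spec.depth) < spec.vaf
    for i, mut in enumerate(is_mut):
        name = f"{site.contig}_{site.pos}_{i:04d}"
        rev = bool(i % 2)
        if not mut or site.label == "true_mutation":
            # fragment start uniform so the mutated-base offset is uniform
            off = int(rng.integers(0, L))
            start = p0 - off
            bases = list(seq[start:start + L])
            if mut:
                bases[off] = site.alt
            reads.append(SimRead(name, site.contig, start, "".join(bases),
                                 f"{L}M", rev))
        elif site.label == "homology_artifact":
            # offset keeps the 5'-anchored 40-mer inside the distant copy
            off = int(rng.integers(4, L - 35))
            start = p0 - off
            bases = list(seq[start:start + L])
            bases[off] = site.alt
            reads.append(SimRead(name, site.contig, start, "".join(bases),
                                 f"{L}M", rev))
        else:  # hairpin artifact: alt pinned near the mapped 3' end,
            # remainder of the read soft-clipped chimeric sequence
            s_pin = site.extra["s_pin"]
            u = int(rng.integers(12, L - s_pin - 20))
            start = p0 - u
            mapped = seq[start:p0] + site.alt + seq[p0 + 1:p0 + 1 + s_pin]
            n_clip = L - len(mapped)
            junk = revcomp(seq[start - n_clip:start])
            reads.append(SimRead(name, site.contig, start, mapped + junk,
                                 f"{len(mapped)}M{n_clip}S", False))
    return reads


def simulate_reads(spec: FixtureSpec, genome: dict[str, str],
                   sites: list[Site]) -> list[SimRead]:
    """Aligned reads for every planted site, coordinate-sorted.

    A fresh generator seeded from ``spec.seed`` makes the read set a
    pure function of (spec, registry)."""
    rng = np.random.default_rng(spec.seed + 1)
    reads: list[SimRead] = []
    for site in sites:
        reads.extend(_reads_for_site(rng, genome, site, spec))
    contigs = {c: i for i, c in enumerate(sorted(genome))}
    reads.sort(key=lambda r: (contigs[r.contig], r.ref_start, r.name))
    return reads


def write_fixture(spec: FixtureSpec, out_dir: str | os.PathLike,
                  ) -> dict[str, Path]:
    """Write reference.fa(+.fai), reads.bam(+.bai), mutations.tsv and
    truth.tsv under ``out_dir``; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome, sites = make_reference(spec)
    reads = simulate_reads(spec, genome, sites)

    fasta = out / "reference.fa"
    with open(fasta, "w") as fh:
        for contig in sorted(genome):
            fh.write(f">{contig}\n")
            s = genome[contig]
            for i in range(0, len(s), 60):
                fh.write(s[i:i + 60] + "\n")
    pysam.faidx(str(fasta))

    bam = out / "reads.bam"
    contigs = sorted(genome)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": len(genome[c])} for c in contigs],
    }
    with pysam.AlignmentFile(str(bam), "wb", header=header) as bh:
        for r in reads:
            a = pysam.AlignedSegment(bh.header)
            a.query_name = r.name
            a.query_sequence = r.seq
            a.flag = 16 if r.is_reverse else 0
            a.reference_id = contigs.index(r.contig)
            a.reference_start = r.ref_start
            a.mapping_quality = 60
            a.cigarstring = r.cigar
            a.query_qualities = pysam.qualitystring_to_array("I" * len(r.seq))
            bh.write(a)
    pysam.index(str(bam))

    mut = out / "mutations.tsv"
    with open(mut, "w") as fh:
        fh.write("Sample\tChr\tPos\tRef\tAlt\n")
        for s in sites:
            fh.write(f"sim\t{s.contig}\t{s.pos}\t{s.ref}\t{s.alt}\n")

    truth = out / "truth.tsv"
    with open(truth, "w") as fh:
        fh.write("Sample\tChr\tPos\tRef\tAlt\tLabel\n")
        for s in sites:
            fh.write(f"sim\t{s.contig}\t{s.pos}\t{s.ref}\t{s.alt}\t{s.label}\n")

    return {"fasta": fasta, "bam": bam, "mutations": mut, "truth": truth}
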