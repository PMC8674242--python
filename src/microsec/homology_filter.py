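"""Distant-homologous-region artifact detection — Filter 4.

The second chimera mechanism: two single-stranded fragments from distant
but locally identical genomic regions mis-anneal during end repair, and
the polymerase copies the one-base difference between them into the
read.  Reads produced this way carry, around the "mutation", a 40-mer
that exists verbatim somewhere else in the genome.

Per supporting read, two 40-base queries are built around a core made of
the mutated bases plus the read bases covering the flanking repeat runs:
one anchored 4 bases 5' of the core and extended 3'-ward to 40 bases,
the other mirrored.  A read matches when either query occurs exactly, on
either strand, outside an exclusion zone around the locus itself.  The
mutation is flagged when more than 15% of supporting reads match.

Matching is one multi-pattern pass over the genome per batch (all
queries checked simultaneously against a hash set), so full-genome runs
scale linearly in genome size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io_formats import MutationRecord
from .read_evidence import ReadEvidence, RepeatContext, revcomp

log = logging.getLogger(__name__)

QUERY_LEN = 40
_ANCHOR = 4
_DNA = frozenset("ACGT")


@dataclass(frozen=True)
class HomologyQueryPair:
    """The two 40-base queries for one supporting read; either member
    may be None when the read is too short on the required side."""

    q_5anchor: str | None
    q_3anchor: str | None
    source_read_id: str

    def queries(self) -> list[str]:
        return [q for q in (self.q_5anchor, self.q_3anchor) if q]


def build_homology_queries(ev: ReadEvidence, record: MutationRecord,
                           repeats: RepeatContext,
                           query_len: int = QUERY_LEN) -> HomologyQueryPair:
    """Build the query pair from one supporting read.

    core = event read bases extended by R5 read bases 5' and R3 read
    bases 3' (the surrounding repeat run as seen in the read).  The
    5'-anchored query prepends 4 read bases and extends 3'-ward to 40;
    the 3'-anchored query mirrors it.
    """
    n = len(ev.seq)
    core_lo = ev.event_q_start - repeats.R5
    core_hi = ev.event_q_end + repeats.R3
    if core_lo < 0 or core_hi > n:
        return HomologyQueryPair(None, None, ev.read_id)
    if (core_hi - core_lo) + _ANCHOR > query_len:
        log.debug("repeat run too long for a %d-base query (read %s)",
                  query_len, ev.read_id)
        return HomologyQueryPair(None, None, ev.read_id)

    q5 = None
    start = core_lo - _ANCHOR
    if start >= 0 and start + query_len <= n:
        q5 = ev.seq[start:start + query_len]
    q3 = None
    end = core_hi + _ANCHOR
    if end <= n and end - query_len >= 0:
        q3 = ev.seq[end - query_len:end]
    return HomologyQueryPair(q5, q3, ev.read_id)


class GenomeMatcher:
    """Exact multi-pattern search over a genome.

    One linear pass per contig: every ``query_len``-mer of the genome is
    looked up in a hash set holding each registered query and its
    reverse complement, so all queries are matched simultaneously.
    Queries containing non-ACGT characters never match.
    """

    def __init__(self, genome: Mapping[str, str], queries: Iterable[str],
                 query_len: int = QUERY_LEN):
        self.query_len = query_len
        pats: dict[str, list[tuple[str, str]]] = {}
        for q in set(queries):
            qu = q.upper()
            if len(qu) != query_len or set(qu) - _DNA:
                continue
            pats.setdefault(qu, []).append((qu, "+"))
            rc = revcomp(qu)
            pats.setdefault(rc, []).append((qu, "-"))
        #: query -> list of (contig, start0, strand) occurrences
        self.hits: dict[str, list[tuple[str, int, str]]] = {}
        if not pats:
            return
        k = query_len
        for contig in sorted(genome.keys()):
            seq = str(genome[contig][:]).upper()
            for i in range(len(seq) - k + 1):
                found = pats.get(seq[i:i + k])
                if found:
                    for q, strand in found:
                        self.hits.setdefault(q, []).append((contig, i, strand))

    def occurrences(self, query: str) -> list[tuple[str, int, str]]:
        return self.hits.get(query.upper(), [])

    def matches_outside(self, query: str, chrom: str, lo: int, hi: int) -> bool:
        """True iff the query occurs on either strand at >=1 position
        whose interval does not overlap the exclusion zone
        [lo, hi) on ``chrom``."""
        for contig, start, _strand in self.occurrences(query):
            if contig != chrom:
                return True
            if start + self.query_len <= lo or start >= hi:
                return True
        return False


def genome_exact_match(query: str, genome: Mapping[str, str],
                       exclusion_zone: tuple[str, int, int],
                       query_len: int = QUERY_LEN) -> bool:
    """Single-query convenience wrapper around :class:`GenomeMatcher`."""
    matcher = GenomeMatcher(genome, [query], query_len)
    chrom, lo, hi = exclusion_zone
    return matcher.matches_outside(query, chrom, lo, hi)


def apply_homology_filter(evidences: Sequence[ReadEvidence],
                          record: MutationRecord,
                          repeats: RepeatContext,
                          genome: Mapping[str, str] | None = None,
                          rate_threshold: float = 0.15,
                          exclusion_pad: int = 200,
                          matcher: GenomeMatcher | None = None,
                          ) -> tuple[bool, float]:
    """Rate of supporting reads with a distant exact 40-mer match; the
    denominator is all supporting reads (reads yielding no valid query
    count as non-matching).  Flagged iff rate strictly exceeds the
    threshold."""
    support = [ev for ev in evidences if ev.supports_mutation]
    if not support:
        return False, 0.0
    pairs = [build_homology_queries(ev, record, repeats) for ev in support]
    if matcher is None:
        if genome is None:
            raise ValueError("either a genome or a prebuilt matcher is required")
        matcher = GenomeMatcher(genome, [q for p in pairs for q in p.queries()])
    ev_lo, ev_hi = record.ref_span
    lo = min(ev_lo, record.pos0) - exclusion_pad
    hi = ev_hi + exclusion_pad
    n_match = sum(
        1 for p in pairs
        if any(matcher.matches_outside(q, record.chrom, lo, hi)
               for q in p.queries())
    )
    rate = n_match / len(support)
    return rate > rate_threshold, rate
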