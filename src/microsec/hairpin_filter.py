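"""Hairpin (palindrome) artifact detection — Filter 2.

A single-stranded fragment carrying two nearby reverse-complementary
segments can fold back on itself during end repair; the polymerase then
copies across the mismatch between the two arms, producing reads whose
sequence around the "mutation" is really the opposite strand of a
neighboring segment.  Such a read is recognized by taking a short window
of the read centered on the mutated bases and asking whether its reverse
complement occurs verbatim in the reference within a fixed distance of
the locus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .io_formats import MutationRecord, MutType
from .read_evidence import ReadEvidence, RepeatContext, revcomp

#: minimum query length; flanks extend it to max(MIN_QUERY, N + 14)
MIN_QUERY = 15
_FLANK = 7


@dataclass(frozen=True)
class HairpinQuery:
    query_seq: str
    source_read_id: str


def extract_hairpin_query(ev: ReadEvidence, record: MutationRecord,
                          ) -> HairpinQuery | None:
    """Window of the read centered on the mutated bases.

    Length is max(15, N + 14): 7 read bases on each flank of the event
    (for deletions, which occupy no read bases, 7 left and 8 right of
    the junction).  Soft-clipped bases are included — they are exactly
    where the chimeric copy lives.  Returns None when the read lacks the
    required flank on either side; such reads count as non-hairpin.
    """
    e0, e1 = ev.event_q_start, ev.event_q_end
    left = _FLANK
    right = _FLANK + 1 if record.mut_type is MutType.DEL else _FLANK
    if e0 - left < 0 or e1 + right > len(ev.seq):
        return None
    return HairpinQuery(ev.seq[e0 - left:e1 + right], ev.read_id)


def is_hairpin_read(query: HairpinQuery | str, neighborhood: str) -> bool:
    """True iff the query's reverse complement occurs exactly in the
    forward reference neighborhood — i.e. the query sits on the opposite
    strand nearby.  Ambiguity codes never match."""
    q = query.query_seq if isinstance(query, HairpinQuery) else query
    if not q or "N" in q:
        return False
    return revcomp(q) in neighborhood.upper()


def apply_hairpin_filter(evidences: Sequence[ReadEvidence],
                         record: MutationRecord,
                         repeats: RepeatContext,
                         rate_threshold: float = 0.5,
                         ) -> tuple[bool, float]:
    """Rate of hairpin-derived reads among mutation-supporting reads;
    flagged iff the rate strictly exceeds the threshold (default: more
    than half)."""
    support = [ev for ev in evidences if ev.supports_mutation]
    if not support:
        return False, 0.0
    n_hairpin = 0
    for ev in support:
        q = extract_hairpin_query(ev, record)
        if q is not None and is_hairpin_read(q, repeats.neighborhood):
            n_hairpin += 1
    rate = n_hairpin / len(support)
    return rate > rate_threshold, rate
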