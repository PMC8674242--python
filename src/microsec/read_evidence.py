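"""Per-read evidence at a mutation locus.

Each aligned read overlapping a called mutation is converted into a
:class:`ReadEvidence`: the 3' sequencing adapter is trimmed, the event is
located within the read by walking the CIGAR, and the 5'/3'/shorter
supporting lengths are computed.

The supporting length on one side of a read is the number of read bases
from the base adjacent to the event to the furthest mapped base on that
side — soft- and hard-clipped bases contribute nothing, read bases
consumed by insertions elsewhere in the alignment do count (read-base
counting, not reference-span counting), and the mutated bases themselves
are excluded from both sides.  5' and 3' are in reference orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pysam

from .io_formats import MutationRecord, MutType

log = logging.getLogger(__name__)

_COMP = str.maketrans("ACGTN", "TGCAN")

# CIGAR numeric ops (pysam encoding)
_M, _I, _D, _N, _S, _H, _EQ, _X = 0, 1, 2, 3, 4, 5, 7, 8
_CONSUMES_QUERY = {_M, _I, _S, _EQ, _X}
_CONSUMES_REF = {_M, _D, _N, _EQ, _X}
_ALIGNED = {_M, _EQ, _X}


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class ReadEvidence:
    """One read's view of a mutation.

    ``seq`` is the post-trim read sequence (soft-clipped bases included;
    they are part of the read and carry the chimeric signal the hairpin
    and homology filters look for).  ``event_q_start``/``event_q_end``
    delimit the event within ``seq`` (empty interval for deletions and,
    on non-supporting reads, for insertions).
    """

    read_id: str
    strand: str                      # "forward" | "reverse"
    seq: str
    qualities: Sequence[int] | None
    cigar_segments: list[tuple[int, int]]
    supports_mutation: bool
    event_q_start: int
    event_q_end: int
    len5: int
    len3: int
    read_len_L: int
    mismatch_count_local: int

    @property
    def shorter_len(self) -> int:
        return min(self.len5, self.len3)


@dataclass(frozen=True)
class RepeatContext:
    """Tandem-repeat run lengths flanking an indel, and the reference
    neighborhood used by the hairpin filter.  R5 = R3 = 0 for SNV/MNV."""

    R5: int
    R3: int
    neighborhood: str
    neighborhood_start: int  # 0-based genomic offset of neighborhood[0]


# ----------------------------------------------------------------------
# adapter trimming


def trim_adapter(sequence: str, qualities: Sequence[int] | None,
                 adapter: str, max_mismatch_rate: float = 0.10,
                 ) -> tuple[str, Sequence[int] | None]:
    """Trim the 3' adapter from a read.

    Removes the longest suffix of ``sequence`` that aligns against a
    prefix of ``adapter`` with a mismatch fraction <= ``max_mismatch_rate``
    (partial-suffix overlaps allowed).  Qualities are trimmed in
    lockstep.  Idempotent; a read with no adapter-like suffix is
    returned unchanged.
    """
    if not adapter:
        raise ValueError("adapter must be nonempty")
    if not 0 <= max_mismatch_rate < 1:
        raise ValueError("max_mismatch_rate must be in [0, 1)")
    ad = adapter.upper()
    end = len(sequence)
    # iterate to a fixpoint: once a suffix is removed, the remaining end
    # may itself align to an adapter prefix (guarantees idempotence)
    changed = True
    while changed and end > 0:
        changed = False
        seq = sequence[:end].upper()
        for start in range(max(0, end - len(ad)), end):
            overlap = end - start
            mm = sum(a != b for a, b in zip(seq[start:], ad[:overlap]))
            if mm <= max_mismatch_rate * overlap:
                end = start
                changed = True
                break
    return (sequence[:end],
            qualities[:end] if qualities is not None else None)


# ----------------------------------------------------------------------
# CIGAR geometry


class _AlnMap:
    """Query<->reference geometry of one alignment, walked once."""

    def __init__(self, cigartuples: Sequence[tuple[int, int]], ref_start: int,
                 query_len: int):
        self.segments = [(op, ln) for op, ln in cigartuples if op != _H]
        q = r = 0
        qlen = sum(ln for op, ln in self.segments if op in _CONSUMES_QUERY)
        if qlen != query_len:
            raise ValueError("CIGAR inconsistent with sequence length")
        self.lead_clip = self.segments[0][1] if self.segments and self.segments[0][0] == _S else 0
        self.tail_clip = self.segments[-1][1] if self.segments and self.segments[-1][0] == _S else 0
        self.query_len = query_len
        # per-op walk records: (op, len, q_start, r_start)
        self.walk: list[tuple[int, int, int, int]] = []
        r = ref_start
        for op, ln in self.segments:
            self.walk.append((op, ln, q, r))
            if op in _CONSUMES_QUERY:
                q += ln
            if op in _CONSUMES_REF:
                r += ln

    def q_of_ref(self, pos0: int) -> tuple[int | None, int | None]:
        """(query offset, op) for a reference position; query offset is
        None when the position is deleted/skipped in the read, (None,
        None) when it is outside the aligned span."""
        for op, ln, q, r in self.walk:
            if op in _CONSUMES_REF and r <= pos0 < r + ln:
                if op in _ALIGNED:
                    return q + (pos0 - r), op
                return None, op
        return None, None

    def find_del(self, ref_lo: int, ref_hi: int) -> int | None:
        """Query offset of the junction if a D op exactly spans
        [ref_lo, ref_hi); else None."""
        for op, ln, q, r in self.walk:
            if op == _D and r == ref_lo and r + ln == ref_hi:
                return q
        return None

    def find_ins(self, junction: int) -> tuple[int, int] | None:
        """(q_start, length) of an I op sitting at reference ``junction``
        (i.e. between junction-1 and junction); else None."""
        for op, ln, q, r in self.walk:
            if op == _I and r == junction:
                return q, ln
        return None


# ----------------------------------------------------------------------
# evidence construction


def _oriented_trim(seq: str, quals, is_reverse: bool, adapters: Sequence[str],
                   max_mismatch_rate: float) -> tuple[int, int]:
    """Return the kept query window [keep_lo, keep_hi) after trimming the
    sequencing-orientation 3' adapter.  For reverse-strand alignments the
    read's 3' end is the left end of the stored (reference-orientation)
    sequence."""
    n = len(seq)
    if not adapters:
        return 0, n
    oriented = revcomp(seq) if is_reverse else seq
    best = n
    for ad in adapters:
        trimmed, _ = trim_adapter(oriented, None, ad, max_mismatch_rate)
        best = min(best, len(trimmed))
    return (n - best, n) if is_reverse else (0, best)


def build_read_evidence(aln: pysam.AlignedSegment,
                        record: MutationRecord,
                        neighborhood: str,
                        neighborhood_start: int,
                        adapters: Sequence[str] = (),
                        max_mismatch_rate: float = 0.10,
                        min_alt_quality: int | None = None,
                        ) -> ReadEvidence | None:
    """Convert one raw alignment into :class:`ReadEvidence`.

    Returns None when the read cannot be placed on either side of the
    mutant/non-mutant partition: the locus falls inside a soft-clip or
    outside the aligned span, or the event was trimmed away with the
    adapter.  Such reads join neither the supporting set nor the null.
    """
    seq = aln.query_sequence
    if seq is None or aln.cigartuples is None:
        return None
    seq = seq.upper()
    try:
        amap = _AlnMap(aln.cigartuples, aln.reference_start, len(seq))
    except ValueError:
        raise ValueError(f"CIGAR inconsistent with sequence length in read "
                         f"{aln.query_name}") from None

    keep_lo, keep_hi = _oriented_trim(seq, aln.query_qualities, aln.is_reverse,
                                      adapters, max_mismatch_rate)
    ev_lo, ev_hi = record.ref_span

    supports = False
    if record.mut_type in (MutType.SNV, MutType.MNV):
        offs = []
        for p in range(ev_lo, ev_hi):
            q, op = amap.q_of_ref(p)
            if op == _S or op is None:
                return None           # locus clipped / not covered
            if q is None:
                offs = None           # deleted in this read
                break
            offs.append(q)
        if offs is None:
            # read carries a deletion over the locus: non-supporting,
            # event interval collapses to the junction
            q0, _ = amap.q_of_ref(ev_lo - 1)
            if q0 is None:
                return None
            e0 = e1 = q0 + 1
        else:
            if offs != list(range(offs[0], offs[0] + record.mut_len_N)):
                return None           # event interrupted by an indel
            e0, e1 = offs[0], offs[0] + record.mut_len_N
            bases = seq[e0:e1]
            supports = bases == record.alt
            if supports and min_alt_quality is not None and aln.query_qualities is not None:
                if min(aln.query_qualities[e0:e1]) < min_alt_quality:
                    supports = False
    elif record.mut_type is MutType.DEL:
        qj = amap.find_del(ev_lo, ev_hi)
        if qj is not None:
            supports = True
            e0 = e1 = qj
        else:
            qs = [amap.q_of_ref(p) for p in (ev_lo, ev_hi - 1)]
            if any(op == _S or op is None for _, op in qs):
                return None
            aligned = [q for q, _ in qs if q is not None]
            if not aligned:
                return None
            e0, e1 = aligned[0], aligned[-1] + 1
    else:  # INS
        hit = amap.find_ins(ev_lo)
        if hit is not None and hit[1] == record.mut_len_N:
            e0 = hit[0]
            e1 = e0 + record.mut_len_N
            supports = seq[e0:e1] == record.unit
            if not supports:
                e0 = e1 = hit[0]      # some other insertion: null read
        else:
            qa, opa = amap.q_of_ref(record.pos0)
            qb, opb = amap.q_of_ref(record.pos0 + 1)
            if opa == _S or opa is None or opb == _S or opb is None or qa is None:
                return None
            e0 = e1 = qa + 1

    if not (keep_lo <= e0 and e1 <= keep_hi):
        return None                   # event trimmed off with the adapter

    # supporting lengths: kept, non-clipped read bases on each side
    len5 = max(0, e0 - max(amap.lead_clip, keep_lo))
    len3 = max(0, min(len(seq) - amap.tail_clip, keep_hi) - e1)

    mm = _local_mismatches(amap, seq, record, neighborhood, neighborhood_start)

    return ReadEvidence(
        read_id=aln.query_name or "",
        strand="reverse" if aln.is_reverse else "forward",
        seq=seq[keep_lo:keep_hi],
        qualities=(list(aln.query_qualities[keep_lo:keep_hi])
                   if aln.query_qualities is not None else None),
        cigar_segments=amap.segments,
        supports_mutation=supports,
        event_q_start=e0 - keep_lo,
        event_q_end=e1 - keep_lo,
        len5=len5,
        len3=len3,
        read_len_L=keep_hi - keep_lo,
        mismatch_count_local=mm,
    )


def _local_mismatches(amap: _AlnMap, seq: str, record: MutationRecord,
                      neighborhood: str, neighborhood_start: int,
                      flank: int = 5) -> int:
    """Mismatched read bases within the ``2*flank`` reference bases
    surrounding the event (the mutated bases themselves excluded)."""
    ev_lo, ev_hi = record.ref_span
    positions = list(range(ev_lo - flank, ev_lo)) + list(range(ev_hi, ev_hi + flank))
    mm = 0
    for p in positions:
        i = p - neighborhood_start
        if not 0 <= i < len(neighborhood):
            continue
        q, op = amap.q_of_ref(p)
        if q is None or op not in _ALIGNED:
            continue
        if seq[q] != neighborhood[i].upper():
            mm += 1
    return mm


# ----------------------------------------------------------------------
# repeat context


def _tandem_run_3p(ref: str, start: int, unit: str) -> int:
    """Bases from ``start`` onward matching tandem copies of ``unit``
    (trailing partial copy counted base-by-base)."""
    n = 0
    while start + n < len(ref) and ref[start + n].upper() == unit[n % len(unit)]:
        n += 1
    return n


def _tandem_run_5p(ref: str, end: int, unit: str) -> int:
    """Bases immediately before ``end`` matching ``unit`` read in reverse
    phase (leading partial copy counted base-by-base)."""
    n = 0
    while end - 1 - n >= 0 and ref[end - 1 - n].upper() == unit[-1 - (n % len(unit))]:
        n += 1
    return n


def compute_repeat_context(reference: Mapping[str, str],
                           record: MutationRecord,
                           window: int = 200) -> RepeatContext:
    """Repeat run lengths R5/R3 around an indel plus the reference
    neighborhood (+-``window`` bases, truncated at contig ends).

    For an indel with unit sequence U, R3 is the maximal stretch
    immediately 3' of the event over which the reference equals tandem
    copies of U; R5 mirrors it with U read in reverse phase.  SNV/MNV
    have R5 = R3 = 0 by definition.
    """
    contig = str(reference[record.chrom][:])
    ev_lo, ev_hi = record.ref_span
    lo = max(0, ev_lo - window)
    hi = min(len(contig), ev_hi + window)
    neigh = contig[lo:hi].upper()
    if record.mut_type in (MutType.SNV, MutType.MNV):
        return RepeatContext(0, 0, neigh, lo)
    unit = record.unit
    r3 = _tandem_run_3p(contig, ev_hi, unit)
    r5 = _tandem_run_5p(contig, ev_lo, unit)
    return RepeatContext(r5, r3, neigh, lo)
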