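"""Readers and writers for every external artifact the pipeline touches.

Coordinate conventions, fixed project-wide:

* external files (mutation TSV, results TSV) are 1-based inclusive;
* internal offsets are 0-based half-open.

``MutationRecord.pos`` keeps the external 1-based coordinate; the
``pos0`` property exposes the internal offset.  Indel alleles are stored
in the anchored (VCF-style) representation; the "-" dialect used by some
callers is normalized on input.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import pysam

log = logging.getLogger(__name__)

_DNA = frozenset("ACGT")

#: Stable column order of the results TSV.
RESULT_COLUMNS = [
    "Sample", "Chr", "Pos", "Ref", "Alt", "Type",
    "ReadDepth", "MutSupportingReads",
    "P_shorter", "P_directional", "HairpinRate", "HomologyRate",
    "Filter1", "Filter2", "Filter3", "Filter4",
    "Exemptions", "Verdict",
]


class MutType(str, Enum):
    SNV = "SNV"
    MNV = "MNV"
    INS = "INS"
    DEL = "DEL"


class Exemption(str, Enum):
    """Conditions under which the positional-bias filter is deliberately
    withheld (or a locus is unfilterable) to avoid over-filtering."""

    RANGE_75PCT = "range_75pct"
    MASS_75PCT = "mass_75pct"
    DENSE_MISMATCH = "dense_mismatch"
    INSUFFICIENT_READS = "insufficient_reads"


def _classify(ref: str, alt: str) -> tuple[MutType, int]:
    if len(ref) == len(alt):
        return (MutType.SNV if len(ref) == 1 else MutType.MNV), len(ref)
    if len(ref) > len(alt):
        if not ref.startswith(alt):
            raise ValueError(f"deletion alleles not anchored: {ref}>{alt}")
        return MutType.DEL, len(ref) - len(alt)
    if not alt.startswith(ref):
        raise ValueError(f"insertion alleles not anchored: {ref}>{alt}")
    return MutType.INS, len(alt) - len(ref)


@dataclass(frozen=True)
class MutationRecord:
    """One called variant in anchored-allele representation.

    ``pos`` is 1-based and points at the first reference base of the
    event (the anchor base for indels).  ``mut_len_N`` is the number of
    substituted bases for SNV/MNV and the number of inserted/deleted
    bases for indels.
    """

    sample_name: str
    chrom: str
    pos: int
    ref: str
    alt: str
    mut_type: MutType = field(init=False)
    mut_len_N: int = field(init=False)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        ref = self.ref.upper()
        alt = self.alt.upper()
        object.__setattr__(self, "ref", ref)
        object.__setattr__(self, "alt", alt)
        if not ref or not alt or (set(ref) | set(alt)) - _DNA:
            raise ValueError(f"non-DNA alleles {ref!r}>{alt!r}")
        if ref == alt:
            raise ValueError("ref and alt identical")
        mut_type, n = _classify(ref, alt)
        object.__setattr__(self, "mut_type", mut_type)
        object.__setattr__(self, "mut_len_N", n)

    # -- internal coordinates (0-based half-open) --------------------

    @property
    def pos0(self) -> int:
        return self.pos - 1

    @property
    def ref_span(self) -> tuple[int, int]:
        """Reference interval occupied by the event.

        SNV/MNV: the substituted bases.  DEL: the deleted bases (the
        anchor base is excluded).  INS: the empty junction interval
        immediately after the anchor base.
        """
        if self.mut_type in (MutType.SNV, MutType.MNV):
            return self.pos0, self.pos0 + self.mut_len_N
        if self.mut_type is MutType.DEL:
            return self.pos0 + len(self.alt), self.pos0 + len(self.ref)
        return self.pos0 + len(self.ref), self.pos0 + len(self.ref)

    @property
    def unit(self) -> str:
        """Inserted/deleted bases for indels, substituted bases otherwise."""
        if self.mut_type is MutType.DEL:
            return self.ref[len(self.alt):]
        if self.mut_type is MutType.INS:
            return self.alt[len(self.ref):]
        return self.alt


def _normalize_row(sample: str, chrom: str, pos: int, ref: str, alt: str,
                   reference: Mapping[str, str] | None) -> MutationRecord:
    """Normalize one TSV row, translating the "-" indel dialect into the
    anchored representation (the anchor base is read from the reference)."""
    ref = ref.strip().upper()
    alt = alt.strip().upper()
    if ref == "-" or alt == "-":
        if reference is None:
            raise ValueError('"-" allele dialect requires a reference genome')
        if ref == "-":  # insertion after pos
            anchor = str(reference[chrom][pos - 1:pos]).upper()
            ref, alt = anchor, anchor + alt
        else:  # deletion of ref starting at pos
            anchor = str(reference[chrom][pos - 2:pos - 1]).upper()
            ref, alt, pos = anchor + ref, anchor, pos - 1
    else:
        # trim shared trailing bases down to the minimal anchored form
        while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
    return MutationRecord(sample, chrom, pos, ref, alt)


def read_mutation_list(path: str | os.PathLike,
                       reference: Mapping[str, str] | None = None,
                       ) -> list[MutationRecord]:
    """Read a tab-separated mutation list with header columns
    ``Sample  Chr  Pos  Ref  Alt``.

    Both the anchored-allele and the "-" indel dialects are accepted;
    malformed rows are rejected with a logged diagnostic and parsing
    continues.  Duplicate rows are collapsed.  An empty file raises.
    """
    records: list[MutationRecord] = []
    seen: set[tuple] = set()
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise ValueError(f"empty mutation list: {path}")
        cols = header.rstrip("\n").split("\t")
        try:
            idx = {k: cols.index(k) for k in ("Sample", "Chr", "Pos", "Ref", "Alt")}
        except ValueError as exc:
            raise ValueError(f"missing required column in {path}: {exc}") from exc
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            try:
                rec = _normalize_row(
                    parts[idx["Sample"]], parts[idx["Chr"]],
                    int(parts[idx["Pos"]]), parts[idx["Ref"]], parts[idx["Alt"]],
                    reference,
                )
            except (ValueError, IndexError, KeyError) as exc:
                log.warning("%s:%d: rejected record (%s)", path, lineno, exc)
                continue
            key = (rec.sample_name, rec.chrom, rec.pos, rec.ref, rec.alt)
            if key in seen:
                continue
            seen.add(key)
            records.append(rec)
    return records


def fetch_reads(bam: pysam.AlignmentFile | str | os.PathLike,
                record: MutationRecord,
                pad: int = 200) -> list[pysam.AlignedSegment]:
    """All primary, non-duplicate alignments whose mapped span overlaps
    the event locus ``[pos, pos + len(ref) - 1]``.

    Secondary, supplementary, unmapped and duplicate-flagged alignments
    are excluded.  Reads with mapping quality 0 are retained.  ``pad``
    widens the fetch window only; the overlap criterion is the locus.
    """
    own = False
    if not isinstance(bam, pysam.AlignmentFile):
        bam = pysam.AlignmentFile(os.fspath(bam), "rb")
        own = True
    try:
        if record.chrom not in bam.references:
            raise ValueError(f"contig {record.chrom!r} absent from BAM header")
        lo = max(0, record.pos0 - pad)
        hi = record.pos0 + len(record.ref) + pad
        span_lo, span_hi = record.pos0, record.pos0 + len(record.ref)
        out = []
        for aln in bam.fetch(record.chrom, lo, hi):
            if (aln.is_unmapped or aln.is_secondary or aln.is_supplementary
                    or aln.is_duplicate):
                continue
            if aln.reference_start < span_hi and aln.reference_end > span_lo:
                out.append(aln)
        return out
    finally:
        if own:
            bam.close()


@dataclass
class ResultRow:
    """Per-mutation verdict with all intermediate filter evidence.

    Filters never drop rows; they annotate.  ``verdict`` is ``artifact``
    iff any of the four filter booleans is set.
    """

    record: MutationRecord
    read_depth: int = 0
    mut_supporting_reads: int = 0
    p_shorter: float = float("nan")
    p_directional: float = float("nan")
    hairpin_read_rate: float = 0.0
    homology_read_rate: float = 0.0
    filter_1: bool = False
    filter_2: bool = False
    filter_3: bool = False
    filter_4: bool = False
    exemption_flags: frozenset[Exemption] = frozenset()

    @property
    def verdict(self) -> str:
        return ("artifact"
                if self.filter_1 or self.filter_2 or self.filter_3 or self.filter_4
                else "pass")

    def to_fields(self) -> list[str]:
        r = self.record

        def prob(x: float) -> str:
            return "NA" if x != x else f"{x:.6e}"

        exem = ",".join(sorted(e.value for e in self.exemption_flags)) or "."
        return [
            r.sample_name, r.chrom, str(r.pos), r.ref, r.alt, r.mut_type.value,
            str(self.read_depth), str(self.mut_supporting_reads),
            prob(self.p_shorter), prob(self.p_directional),
            f"{self.hairpin_read_rate:.6f}", f"{self.homology_read_rate:.6f}",
            *(("TRUE" if f else "FALSE")
              for f in (self.filter_1, self.filter_2, self.filter_3, self.filter_4)),
            exem, self.verdict,
        ]


def write_results(rows: Sequence[ResultRow], path: str | os.PathLike) -> None:
    """Write the results TSV with the stable :data:`RESULT_COLUMNS` order."""
    with open(path, "w") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(row.to_fields()) + "\n")


def read_results(path: str | os.PathLike) -> list[dict]:
    """Read a results TSV back into dictionaries (round-trip support)."""
    out = []
    with open(path) as fh:
        cols = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            vals = line.rstrip("\n").split("\t")
            d = dict(zip(cols, vals))
            d["Pos"] = int(d["Pos"])
            for k in ("Filter1", "Filter2", "Filter3", "Filter4"):
                d[k] = d[k] == "TRUE"
            for k in ("P_shorter", "P_directional"):
                d[k] = float("nan") if d[k] == "NA" else float(d[k])
            for k in ("HairpinRate", "HomologyRate"):
                d[k] = float(d[k])
            out.append(d)
    return out
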