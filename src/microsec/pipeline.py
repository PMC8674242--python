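"""Per-mutation orchestration of evidence extraction and the four filters.

For each called mutation the pipeline fetches the overlapping reads,
builds :class:`~microsec.read_evidence.ReadEvidence`, then applies

* Filter 1 — positional-bias test on the shorter supporting length;
* Filter 2 — hairpin (palindrome) read detection;
* Filter 3 — positional-bias tests on the 5' and 3' supporting lengths
  separately (flag if either trips);
* Filter 4 — distant exact-homology read detection.

The combined verdict is *artifact* iff any filter flags.  Filters
annotate, never drop: one row per input mutation, order preserved, and
one mutation's failure never aborts the batch.  Homology queries are
pooled across the whole batch into a single genome pass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pysam
from pyfaidx import Fasta

from . import hairpin_filter, homology_filter, length_filter
from .io_formats import (Exemption, MutationRecord, ResultRow, fetch_reads,
                         read_mutation_list, write_results)
from .read_evidence import (ReadEvidence, RepeatContext, build_read_evidence,
                            compute_repeat_context)

log = logging.getLogger(__name__)

#: loci with fewer covering reads than this get a coverage warning;
#: below this depth the positional-bias test loses power
LOW_DEPTH_WARNING = 100


@dataclass(frozen=True)
class PipelineConfig:
    """Run parameters.  ``read_length_L`` is only a sanity reference;
    the per-read post-trim length is what enters the statistics."""

    read_length_L: int = 150
    adapters: tuple[str, ...] = ()
    p_threshold: float = 1e-6
    hairpin_window: int = 200
    hairpin_min_len: int = 15
    hairpin_rate: float = 0.5
    homology_len: int = 40
    homology_rate: float = 0.15
    exemption_fraction: float = 0.75
    adapter_mismatch_rate: float = 0.10
    min_alt_quality: int | None = None
    null_from_mutant_reads: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length_L <= 0:
            raise ValueError("read_length_L must be positive")
        for name in ("p_threshold", "hairpin_rate", "homology_rate",
                     "exemption_fraction", "adapter_mismatch_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} out of range: {v}")


@dataclass
class LocusEvidence:
    """Evidence bundle for one mutation, prior to the filter verdicts."""

    record: MutationRecord
    evidences: list[ReadEvidence]
    repeats: RepeatContext
    n_excluded: int = 0
    error: str | None = None

    @property
    def support(self) -> list[ReadEvidence]:
        return [e for e in self.evidences if e.supports_mutation]

    @property
    def null(self) -> list[ReadEvidence]:
        return [e for e in self.evidences if not e.supports_mutation]


def gather_evidence(record: MutationRecord,
                    alns: Sequence[pysam.AlignedSegment],
                    reference: Mapping[str, str],
                    config: PipelineConfig) -> LocusEvidence:
    repeats = compute_repeat_context(reference, record,
                                     window=config.hairpin_window)
    evidences: list[ReadEvidence] = []
    n_excluded = 0
    for aln in alns:
        ev = build_read_evidence(
            aln, record, repeats.neighborhood, repeats.neighborhood_start,
            adapters=config.adapters,
            max_mismatch_rate=config.adapter_mismatch_rate,
            min_alt_quality=config.min_alt_quality)
        if ev is None:
            n_excluded += 1
        else:
            evidences.append(ev)
    return LocusEvidence(record, evidences, repeats, n_excluded)


def _length_verdict(loc: LocusEvidence, config: PipelineConfig,
                    ) -> tuple[bool, bool, float, float, set[Exemption]]:
    """Filters 1 and 3.  Returns (filter_1, filter_3, p_shorter,
    p_directional, exemptions)."""
    support = loc.support
    null = loc.support if config.null_from_mutant_reads else loc.null
    rec = loc.record
    N = rec.mut_len_N
    L = max((e.read_len_L for e in loc.evidences), default=config.read_length_L)
    dense = any(e.mismatch_count_local > 3 for e in support)

    exemptions: set[Exemption] = set()
    results: dict[str, length_filter.SupportingLengthStats] = {}
    for which in ("shorter", "five_prime", "three_prime"):
        try:
            C, D = length_filter.theoretical_bounds(rec.mut_type, N, L,
                                                    loc.repeats.R5,
                                                    loc.repeats.R3, which)
        except ValueError:
            log.warning("%s:%d unfilterable by length (N=%d, L=%d)",
                        rec.chrom, rec.pos, N, L)
            exemptions.add(Exemption.INSUFFICIENT_READS)
            continue
        vals = {"shorter": [e.shorter_len for e in support],
                "five_prime": [e.len5 for e in support],
                "three_prime": [e.len3 for e in support]}[which]
        nvals = {"shorter": [e.shorter_len for e in null],
                 "five_prime": [e.len5 for e in null],
                 "three_prime": [e.len3 for e in null]}[which]
        stats = length_filter.evaluate_statistic(
            vals, nvals, C, D, dense_mismatch=dense,
            exemption_fraction=config.exemption_fraction)
        results[which] = stats
        exemptions |= stats.exemptions

    def flag(which: str) -> bool:
        return (which in results and
                length_filter.apply_length_filter(results[which],
                                                  config.p_threshold))

    def p_of(which: str) -> float:
        return results[which].p if which in results else float("nan")

    p_dir = min((p_of("five_prime"), p_of("three_prime")),
                key=lambda x: (x != x, x))  # NaN sorts last
    return (flag("shorter"), flag("five_prime") or flag("three_prime"),
            p_of("shorter"), p_dir, exemptions)


def classify_mutation(record: MutationRecord,
                      alns: Sequence[pysam.AlignedSegment],
                      reference: Mapping[str, str],
                      config: PipelineConfig,
                      matcher: homology_filter.GenomeMatcher | None = None,
                      ) -> ResultRow:
    """Run all four filters for one mutation and combine the verdicts."""
    loc = gather_evidence(record, alns, reference, config)
    return classify_from_evidence(loc, reference, config, matcher)


def classify_from_evidence(loc: LocusEvidence,
                           reference: Mapping[str, str],
                           config: PipelineConfig,
                           matcher: homology_filter.GenomeMatcher | None = None,
                           ) -> ResultRow:
    record = loc.record
    row = ResultRow(record, read_depth=len(loc.evidences),
                    mut_supporting_reads=len(loc.support))
    if len(loc.evidences) < LOW_DEPTH_WARNING:
        log.warning("%s:%d locus depth %d < %d; positional-bias test "
                    "has reduced power", record.chrom, record.pos,
                    len(loc.evidences), LOW_DEPTH_WARNING)
    if not loc.support:
        row.exemption_flags = frozenset({Exemption.INSUFFICIENT_READS})
        return row

    f1, f3, p_sh, p_dir, exemptions = _length_verdict(loc, config)
    f2, hp_rate = hairpin_filter.apply_hairpin_filter(
        loc.evidences, record, loc.repeats, rate_threshold=config.hairpin_rate)
    f4, hom_rate = homology_filter.apply_homology_filter(
        loc.evidences, record, loc.repeats, genome=reference,
        rate_threshold=config.homology_rate,
        exclusion_pad=config.hairpin_window, matcher=matcher)

    row.p_shorter = p_sh
    row.p_directional = p_dir
    row.hairpin_read_rate = hp_rate
    row.homology_read_rate = hom_rate
    row.filter_1, row.filter_2, row.filter_3, row.filter_4 = f1, f2, f3, f4
    row.exemption_flags = frozenset(exemptions)
    return row


def run_pipeline(mutations_path, bam_path, fasta_path,
                 config: PipelineConfig | None = None,
                 out_path=None) -> dict[str, int]:
    """Run the whole batch; returns summary counts per filter.

    One :class:`ResultRow` per input mutation, order-preserving and
    deterministic given identical inputs and config.  Homology queries
    from every mutation are pooled into a single genome pass.
    """
    config = config or PipelineConfig()
    reference = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
    bam = pysam.AlignmentFile(str(bam_path), "rb")
    bam_contigs = set(bam.references)
    records = read_mutation_list(mutations_path, reference=reference)

    missing = sorted({r.chrom for r in records if r.chrom not in bam_contigs})
    if missing:
        raise ValueError(f"contigs absent from BAM header: {', '.join(missing)}")
    fasta_missing = sorted({r.chrom for r in records
                            if r.chrom not in reference.keys()})
    if fasta_missing:
        raise ValueError("contig-name mismatch between mutation list and "
                         f"FASTA: {', '.join(fasta_missing)}")

    # phase 1: evidence + pooled homology queries
    loci: list[LocusEvidence] = []
    all_queries: list[str] = []
    for rec in records:
        try:
            alns = fetch_reads(bam, rec, pad=config.hairpin_window)
            loc = gather_evidence(rec, alns, reference, config)
        except Exception as exc:  # one bad mutation never kills the batch
            log.error("%s:%d failed: %s", rec.chrom, rec.pos, exc)
            loc = LocusEvidence(rec, [], RepeatContext(0, 0, "", 0),
                                error=str(exc))
        loci.append(loc)
        for ev in loc.support:
            pair = homology_filter.build_homology_queries(
                ev, loc.record, loc.repeats, query_len=config.homology_len)
            all_queries.extend(pair.queries())
    matcher = homology_filter.GenomeMatcher(reference, all_queries,
                                            query_len=config.homology_len)

    # phase 2: verdicts
    rows: list[ResultRow] = []
    for loc in loci:
        if loc.error is not None:
            row = ResultRow(loc.record)
            row.exemption_flags = frozenset({Exemption.INSUFFICIENT_READS})
            rows.append(row)
            continue
        rows.append(classify_from_evidence(loc, reference, config, matcher))
    bam.close()

    if out_path is not None:
        write_results(rows, out_path)

    summary = {
        "total": len(rows),
        "removed_by_filter_1": sum(r.filter_1 for r in rows),
        "removed_by_filter_2": sum(r.filter_2 for r in rows),
        "removed_by_filter_3": sum(r.filter_3 for r in rows),
        "removed_by_filter_4": sum(r.filter_4 for r in rows),
        "removed_by_any_filter": sum(r.verdict == "artifact" for r in rows),
        "passing": sum(r.verdict == "pass" for r in rows),
    }
    log.info("summary: %s", summary)
    return summary
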