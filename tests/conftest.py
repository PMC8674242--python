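from __future__ import annotations

import pysam
import pytest

from microsec.synthetic_fixtures import FixtureSpec, write_fixture


def make_header(contigs: dict[str, int]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": n} for c, n in contigs.items()],
    })


def make_aln(header: pysam.AlignmentHeader, name: str, contig: str,
             ref_start: int, cigar: str, seq: str, *,
             reverse: bool = False, duplicate: bool = False,
             secondary: bool = False, mapq: int = 60,
             quals: str | None = None) -> pysam.AlignedSegment:
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.query_sequence = seq
    flag = 0
    if reverse:
        flag |= 16
    if duplicate:
        flag |= 1024
    if secondary:
        flag |= 256
    a.flag = flag
    a.reference_id = list(header.references).index(contig)
    a.reference_start = ref_start
    a.mapping_quality = mapq
    a.cigarstring = cigar
    a.query_qualities = pysam.qualitystring_to_array(quals or "I" * len(seq))
    return a


def write_bam(path, header: pysam.AlignmentHeader,
              alns: list[pysam.AlignedSegment]) -> str:
    alns = sorted(alns, key=lambda a: (a.reference_id, a.reference_start))
    with pysam.AlignmentFile(str(path), "wb", header=header) as fh:
        for a in alns:
            fh.write(a)
    pysam.index(str(path))
    return str(path)


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory):
    """A small but complete planted data set: 5 sites of each class at
    depth 120 on a 60 kb genome."""
    out = tmp_path_factory.mktemp("fixture")
    spec = FixtureSpec(genome_length=60_000, n_true=5, n_hairpin=5,
                       n_homology=5, depth=120, seed=11)
    paths = write_fixture(spec, out)
    return spec, paths
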