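import random

import pytest
from hypothesis import given, settings, strategies as st

from microsec.io_formats import MutationRecord
from microsec.read_evidence import (build_read_evidence,
                                    compute_repeat_context, revcomp,
                                    trim_adapter)

from conftest import make_aln, make_header

ADAPTER = "AGATCGGAAGAGC"  # 13 bases
HEADER = make_header({"chr1": 100_000})

random.seed(0)
GENOME = {"chr1": "".join(random.choice("ACGT") for _ in range(100_000))}


def _neigh(record, window=200):
    ctx = compute_repeat_context(GENOME, record, window)
    return ctx.neighborhood, ctx.neighborhood_start


def _evidence(cigar, seq, record, ref_start, adapters=(), **kw):
    aln = make_aln(HEADER, "r1", "chr1", ref_start, cigar, seq, **kw)
    neigh, nstart = _neigh(record)
    return build_read_evidence(aln, record, neigh, nstart, adapters=adapters)


def _read_from_ref(start, length, mutate=None):
    bases = list(GENOME["chr1"][start:start + length])
    if mutate:
        off, b = mutate
        bases[off] = b
    return "".join(bases)


class TestTrimAdapter:
    def test_exact_full_adapter_suffix_removed(self):
        seq = "ACGTACGT" + ADAPTER
        out, _ = trim_adapter(seq, None, ADAPTER)
        assert out == "ACGTACGT"

    def test_one_mismatch_in_13_within_rate(self):
        ad = list(ADAPTER)
        ad[5] = "T" if ad[5] != "T" else "A"
        seq = "ACGTACGT" + "".join(ad)   # 1/13 = 7.7% <= 10%
        out, _ = trim_adapter(seq, None, ADAPTER)
        assert out == "ACGTACGT"

    def test_no_adapter_like_suffix_unchanged(self):
        seq = "ACGTACGTACGTGGGG"
        assert trim_adapter(seq, None, "TTTTTTTTTTTTT")[0] == seq

    def test_partial_suffix_overlap(self):
        seq = "ACGTACGT" + ADAPTER[:6]
        out, _ = trim_adapter(seq, None, ADAPTER)
        assert out == "ACGTACGT"

    def test_qualities_trimmed_in_lockstep(self):
        seq = "ACGTACGT" + ADAPTER
        quals = list(range(len(seq)))
        out, q = trim_adapter(seq, quals, ADAPTER)
        assert len(q) == len(out) == 8

    @given(st.text(alphabet="ACGT", min_size=0, max_size=60))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_never_longer_and_idempotent(self, seq):
        out, _ = trim_adapter(seq, None, ADAPTER)
        assert len(out) <= len(seq)
        assert trim_adapter(out, None, ADAPTER)[0] == out


class TestLocateMutation:
    def test_snv_alt_and_ref_reads(self):
        rec = MutationRecord("s", "chr1", 1001, GENOME["chr1"][1000],
                             "C" if GENOME["chr1"][1000] != "C" else "G")
        alt_read = _read_from_ref(950, 150, mutate=(50, rec.alt))
        ref_read = _read_from_ref(950, 150)
        ev_alt = _evidence("150M", alt_read, rec, 950)
        ev_ref = _evidence("150M", ref_read, rec, 950)
        assert ev_alt.supports_mutation and ev_alt.event_q_start == 50
        assert not ev_ref.supports_mutation

    def test_locus_in_soft_clip_excluded(self):
        rec = MutationRecord("s", "chr1", 1001, GENOME["chr1"][1000], "C"
                             if GENOME["chr1"][1000] != "C" else "G")
        # aligned part starts at ref 1010: locus sits in the 30 clipped bases
        seq = "T" * 30 + _read_from_ref(1010, 120)
        assert _evidence("30S120M", seq, rec, 1010) is None

    def test_cigar_inconsistent_raises(self):
        rec = MutationRecord("s", "chr1", 1001, GENOME["chr1"][1000], "C"
                             if GENOME["chr1"][1000] != "C" else "G")
        with pytest.raises(ValueError, match="r1"):
            _evidence("150M", "ACGT" * 10, rec, 950)

    def test_deletion_supporting_read(self):
        ref = GENOME["chr1"][1000:1003]
        rec = MutationRecord("s", "chr1", 1001, ref, ref[0])  # 2-base DEL
        seq = _read_from_ref(941, 60) + _read_from_ref(1003, 88)
        ev = _evidence("60M2D88M", seq, rec, 941)
        assert ev.supports_mutation

    def test_insertion_supporting_read(self):
        anchor = GENOME["chr1"][1000]
        rec = MutationRecord("s", "chr1", 1001, anchor, anchor + "AG")
        seq = _read_from_ref(941, 60) + "AG" + _read_from_ref(1001, 88)
        ev = _evidence("60M2I88M", seq, rec, 941)
        assert ev.supports_mutation and ev.event_q_start == 60
        # same CIGAR but wrong inserted bases: a null read, not supporting
        seq2 = _read_from_ref(941, 60) + "TT" + _read_from_ref(1001, 88)
        ev2 = _evidence("60M2I88M", seq2, rec, 941)
        assert ev2 is not None and not ev2.supports_mutation


class TestSupportingLengths:
    def test_snv_mid_read(self):
        rec = MutationRecord("s", "chr1", 1001, GENOME["chr1"][1000],
                             "C" if GENOME["chr1"][1000] != "C" else "G")
        ev = _evidence("150M", _read_from_ref(990, 150, mutate=(10, rec.alt)),
                       rec, 990)
        assert (ev.len5, ev.len3, ev.shorter_len) == (10, 139, 10)
        assert ev.len5 + ev.len3 + rec.mut_len_N == ev.read_len_L

    def test_snv_at_first_matched_base_after_clip(self):
        rec = MutationRecord("s", "chr1", 1001, GENOME["chr1"][1000],
                             "C" if GENOME["chr1"][1000] != "C" else "G")
        seq = "T" * 20 + _read_from_ref(1000, 130, mutate=(0, rec.alt))
        ev = _evidence("20S130M", seq, rec, 1000)
        assert (ev.len5, ev.len3, ev.shorter_len) == (0, 129, 0)

    def test_deletion_junction_lengths(self):
        ref = GENOME["chr1"][1000:1003]
        rec = MutationRecord("s", "chr1", 1001, ref, ref[0])
        seq = _read_from_ref(941, 60) + _read_from_ref(1003, 88)
        ev = _evidence("60M2D88M", seq, rec, 941)
        assert (ev.len5, ev.len3, ev.shorter_len) == (60, 88, 60)
        assert ev.len5 + ev.len3 == 148  # deletions occupy no read bases

    def test_adapter_trim_shortens_len3(self):
        rec = MutationRecord("s", "chr1", 1001, GENOME["chr1"][1000],
                             "C" if GENOME["chr1"][1000] != "C" else "G")
        core = _read_from_ref(960, 100, mutate=(40, rec.alt))
        seq = core + ADAPTER  # adapter beyond the mapped part, soft-clipped
        ev = _evidence("100M13S", seq, rec, 960, adapters=(ADAPTER,))
        assert ev.read_len_L == 100
        assert (ev.len5, ev.len3) == (40, 59)

    def test_orientation_swap_mirrors_lengths(self):
        """Reverse-complementing the whole fixture swaps len5 and len3
        and leaves the shorter length invariant."""
        rec = MutationRecord("s", "chr1", 1001, GENOME["chr1"][1000],
                             "C" if GENOME["chr1"][1000] != "C" else "G")
        seq = "T" * 20 + _read_from_ref(1000, 130, mutate=(0, rec.alt))
        ev = _evidence("20S130M", seq, rec, 1000)
        assert ev.supports_mutation

        glen = len(GENOME["chr1"])
        mirror = {"chr1": revcomp(GENOME["chr1"])}
        mpos0 = glen - 1 - 1000
        mrec = MutationRecord("s", "chr1", mpos0 + 1, revcomp(rec.ref),
                              revcomp(rec.alt))
        mseq = revcomp(seq)
        mstart = glen - (1000 + 130)   # mapped span mirrors
        aln = make_aln(HEADER, "r1", "chr1", mstart, "130M20S", mseq)
        ctx = compute_repeat_context(mirror, mrec, 200)
        mev = build_read_evidence(aln, mrec, ctx.neighborhood,
                                  ctx.neighborhood_start)
        assert (mev.len5, mev.len3) == (ev.len3, ev.len5)
        assert mev.shorter_len == ev.shorter_len


class TestRepeatContext:
    def _ctx(self, genome, rec):
        return compute_repeat_context(genome, rec, window=50)

    def test_homopolymer_deletion(self):
        g = {"c": "GGGGGGGGGGCAAAAG" + "T" * 50}
        # delete the first A (pos0 11): context C[A]AAAG
        rec = MutationRecord("s", "c", 11, "CA", "C")
        ctx = self._ctx(g, rec)
        assert (ctx.R5, ctx.R3) == (0, 3)

    def test_dinucleotide_deletion(self):
        g = {"c": "GGGGGGGGGGT" + "AGAGAG" + "C" + "T" * 50}
        # delete the first AG: context T[AG]AGAGC
        rec = MutationRecord("s", "c", 11, "TAG", "T")
        ctx = self._ctx(g, rec)
        assert ctx.R3 == 4 and ctx.R5 == 0

    def test_snv_has_no_repeat_context(self):
        g = {"c": "A" * 100}
        rec = MutationRecord("s", "c", 50, "A", "G")
        ctx = self._ctx(g, rec)
        assert (ctx.R5, ctx.R3) == (0, 0)

    def test_insertion_partial_trailing_copy(self):
        g = {"c": "GGGGGGGGGGT" + "AGAAGAA" + "C" + "T" * 50}
        # insert AGA after the T: 3'-ward the reference reads AGA AGA A...
        rec = MutationRecord("s", "c", 11, "T", "TAGA")
        ctx = self._ctx(g, rec)
        assert ctx.R3 == 7 and ctx.R5 == 0

    @given(st.integers(0, 10_000))
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_matches_exhaustive_extension_oracle(self, seed):
        rng = random.Random(seed)
        n = rng.randint(1, 3)
        unit = "".join(rng.choice("ACGT") for _ in range(n))
        left = "".join(rng.choice("ACGT") for _ in range(25))
        right = "".join(rng.choice("ACGT") for _ in range(25))
        g = {"c": left + right}
        rec = MutationRecord("s", "c", len(left), left[-1], left[-1] + unit)
        ctx = compute_repeat_context(g, rec, window=50)

        # oracle: test every candidate extension length explicitly
        def tandem(k):
            return (unit * (k // n + 1))[:k]

        r3 = max((k for k in range(0, len(right) + 1)
                  if right[:k] == tandem(k)), default=0)
        rev = left[:len(left)]
        r5 = max((k for k in range(0, len(left) + 1)
                  if k == 0 or rev[-k:] == (unit * (k // n + 1))[-k:]),
                 default=0)
        assert (ctx.R5, ctx.R3) == (r5, r3)
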