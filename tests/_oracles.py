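"""Independent brute-force oracles used by the tests and the acceptance
script.  Everything here is deliberately naive — exhaustive enumeration
and direct string scanning — and never calls into the code paths it
checks."""

from __future__ import annotations

import random
from fractions import Fraction

_COMP = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ----------------------------------------------------------------------
# placement oracle for theoretical supporting-length bounds
#
# A read placed over the mutated template supports the mutation iff:
#   * substitutions: it simply covers all N mutated bases (a substituted
#     base maps like any other; the achievable lengths are geometric);
#   * indels: each flank (i) contains the entire adjacent repeat run as
#     measured on the actual template by string scanning, because a read
#     ending inside the run is gaplessly consistent with the reference,
#     and (ii) has at least N+1 anchor bases, because keeping the gap
#     scores m - (N+6) against the flat soft-clip penalty of 5, so the
#     gap survives only when m >= N+1 (ties kept).
# The achievable (len5, len3) pairs are collected by enumerating every
# placement; sequences are built with explicit break bases so the repeat
# runs measured on the strings are exactly R5 and R3.


def _make_unit(n: int, rng: random.Random) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def _repeat_3p(unit: str, r: int) -> str:
    return "".join(unit[i % len(unit)] for i in range(r))


def _repeat_5p(unit: str, r: int) -> str:
    return "".join(unit[-1 - (i % len(unit))] for i in range(r))[::-1]


def _break_base(avoid: str, rng: random.Random) -> str:
    return rng.choice([b for b in "ACGT" if b != avoid])


def _scan_run_3p(s: str, start: int, unit: str) -> int:
    n = 0
    while start + n < len(s) and s[start + n] == unit[n % len(unit)]:
        n += 1
    return n


def _scan_run_5p(s: str, end: int, unit: str) -> int:
    n = 0
    while end - 1 - n >= 0 and s[end - 1 - n] == unit[-1 - (n % len(unit))]:
        n += 1
    return n


def placement_oracle(mut_type: str, N: int, L: int, R5: int, R3: int,
                     seed: int = 0) -> set[tuple[int, int]]:
    """Achievable (len5, len3) pairs for mutation-supporting reads of
    length L, by exhaustive placement enumeration."""
    rng = random.Random((seed, mut_type, N, L, R5, R3).__hash__() & 0x7FFFFFFF)
    if mut_type in ("SNV", "MNV"):
        return {(k, L - N - k) for k in range(0, L - N + 1)}

    unit = _make_unit(N, rng)
    rep5 = _repeat_5p(unit, R5)
    rep3 = _repeat_3p(unit, R3)
    # break bases stop the runs from extending into the fillers
    b5 = _break_base(_repeat_5p(unit, R5 + 1)[0], rng)
    b3 = _break_base(_repeat_3p(unit, R3 + 1)[-1], rng)
    filler5 = _make_unit(L, rng) + b5
    filler3 = b3 + _make_unit(L, rng)

    if mut_type == "DEL":
        # reference carries the deleted copy; template lacks it
        template = filler5 + rep5 + rep3 + filler3
        junction = len(filler5) + len(rep5)
    elif mut_type == "INS":
        template = filler5 + rep5 + unit + rep3 + filler3
        junction = len(filler5) + len(rep5)          # first inserted base
    else:
        raise ValueError(mut_type)

    run3 = (_scan_run_3p(template, junction + (N if mut_type == "INS" else 0), unit))
    run5 = _scan_run_5p(template, junction, unit)
    event_len = N if mut_type == "INS" else 0

    out: set[tuple[int, int]] = set()
    for s in range(0, len(template) - L + 1):
        e0 = junction - s                  # event start within the read
        e1 = e0 + event_len
        if e0 < 1 or e1 > L - 1:
            continue                       # needs >=1 base on each side
        len5, len3 = e0, L - e1
        if len5 < max(run5, N + 1) or len3 < max(run3, N + 1):
            continue
        out.add((len5, len3))
    return out


def oracle_bounds(pairs: set[tuple[int, int]], which: str,
                  ) -> tuple[int, int] | None:
    """Min/max of one statistic over the achievable pairs (None if no
    placement supports the mutation)."""
    if not pairs:
        return None
    vals = {"five_prime": [a for a, _ in pairs],
            "three_prime": [b for _, b in pairs],
            "shorter": [min(a, b) for a, b in pairs]}[which]
    return min(vals), max(vals)


# ----------------------------------------------------------------------
# exact multinomial probability


def exact_multinomial_p(f: dict[int, int], A: int, B: int, C: int, D: int,
                        E: int) -> Fraction:
    num = sum(c for x, c in f.items() if A <= x <= B)
    den = sum(c for x, c in f.items() if C <= x <= D)
    return Fraction(num, den) ** E


# ----------------------------------------------------------------------
# brute-force genome scanning


def brute_occurrences(genome: dict[str, str], query: str,
                      ) -> list[tuple[str, int, str]]:
    """Every exact occurrence of query (both strands) over the genome,
    as (contig, start0, strand), by repeated str.find."""
    hits = []
    for contig in sorted(genome):
        seq = genome[contig]
        for pat, strand in ((query, "+"), (rc(query), "-")):
            i = seq.find(pat)
            while i != -1:
                hits.append((contig, i, strand))
                i = seq.find(pat, i + 1)
    return sorted(set(hits))


def brute_hairpin(query: str, window: str) -> bool:
    """Sliding-window comparison: does rc(query) occur in window?"""
    pat = rc(query)
    k = len(pat)
    return any(window[i:i + k] == pat for i in range(len(window) - k + 1))
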