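"""Positional-bias test on supporting lengths (Filters 1 and 3).

A chimeric artifact read can only display the false mutation near one of
its effective ends, so over the mutation-supporting reads the supporting
lengths occupy a suspiciously narrow band.  The test compares the
observed band [A, B] against the band [C, D] that the aligner could
theoretically have produced, using the empirical distribution f of
supporting lengths among the non-mutant reads at the same locus:

    p = ( sum_{m=A..B} f(m) / sum_{n=C..D} f(n) ) ** E

with E the mutant read depth.  Mutations with p below a threshold
(default 1e-6) are flagged, unless an exemption applies: the observed
band covers more than 75% of the theoretical band in width or in null
mass (deep sequencing makes p vanish for perfectly ordinary spreads), or
there are no null reads to build f from.

Filter 1 applies the test to the shorter supporting length, Filter 3 to
the 5' and 3' supporting lengths separately.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_formats import Exemption, MutType

log = logging.getLogger(__name__)

Side = str  # "five_prime" | "three_prime" | "shorter"


def theoretical_bounds(mut_type: MutType, N: int, L: int, R5: int, R3: int,
                       which: Side) -> tuple[int, int]:
    """Theoretical supporting-length range [C, D] achievable by the
    aligner for a mutation-supporting read.

    Substitutions can sit anywhere in a read, so the directional lengths
    span [0, L-N].  Indel-supporting reads must contain the full
    flanking repeat runs (R5, R3) and enough anchor beyond the gap that
    keeping it beats soft-clipping (at least N+1 matching bases, from
    the aligner's gap penalty N+6 against the flat clip penalty 5),
    which floors each side at max(R, N+1).
    """
    if not (L > N >= 1) or R5 < 0 or R3 < 0:
        raise ValueError(f"invalid bounds query N={N} L={L} R5={R5} R3={R3}")
    if mut_type in (MutType.SNV, MutType.MNV):
        if which == "shorter":
            return 0, (L - N) // 2
        return 0, L - N
    need5 = max(R5, N + 1)
    need3 = max(R3, N + 1)
    if mut_type is MutType.DEL:
        if which == "shorter":
            return min(need3, need5), L // 2
        if which == "three_prime":
            return need3, L - need5
        return need5, L - need3
    # INS
    if which == "shorter":
        return min(need3, need5), (L - N) // 2
    if which == "three_prime":
        return need3, L - N - need5
    return need5, L - N - need3


@dataclass
class SupportingLengthStats:
    """Observed band [A, B], theoretical band [C, D], mutant depth E,
    null distribution f and the resulting probability for one statistic."""

    A: int
    B: int
    C: int
    D: int
    E: int
    f: dict[int, int]
    p: float = float("nan")
    exemptions: set[Exemption] = field(default_factory=set)
    used_uniform_fallback: bool = False


def null_distribution(values: Iterable[int]) -> dict[int, int]:
    """Empirical counts of supporting lengths among non-mutant reads."""
    f: dict[int, int] = {}
    for v in values:
        f[v] = f.get(v, 0) + 1
    return f


def _band_sum(f: Mapping[int, int], lo: int, hi: int) -> int:
    return sum(c for x, c in f.items() if lo <= x <= hi)


def multinomial_p(f: Mapping[int, int], A: int, B: int, C: int, D: int,
                  E: int) -> float:
    """Probability that all E mutant supporting lengths fall within
    [A, B] when drawn from f restricted to [C, D]; computed in log space
    when the direct power would underflow."""
    num = _band_sum(f, A, B)
    den = _band_sum(f, C, D)
    if den <= 0:
        raise ZeroDivisionError("null distribution has no mass on [C, D]")
    if num == 0:
        return 0.0
    if num >= den:
        return 1.0
    log_p = E * (math.log(num) - math.log(den))
    if log_p > -700.0:
        return (num / den) ** E
    return math.exp(log_p)


def evaluate_statistic(support_values: Sequence[int],
                       null_values: Sequence[int],
                       C: int, D: int,
                       dense_mismatch: bool = False,
                       exemption_fraction: float = 0.75,
                       ) -> SupportingLengthStats:
    """Build :class:`SupportingLengthStats` for one statistic.

    ``dense_mismatch`` (more than three mismatched bases within the ten
    bases surrounding the mutation on some supporting read) zeroes the
    theoretical minimum before testing, because clustered mutations
    inflate the aligner's minimum anchor requirement.  Observed values
    outside [C, D] are clamped in (and logged): they reflect alignment
    quirks, not impossibilities worth crashing over.
    """
    E = len(support_values)
    exemptions: set[Exemption] = set()
    if dense_mismatch:
        C = 0
        exemptions.add(Exemption.DENSE_MISMATCH)
    if E == 0 or not null_values:
        exemptions.add(Exemption.INSUFFICIENT_READS)
        return SupportingLengthStats(0, 0, C, D, E, {}, float("nan"), exemptions)
    if C > D:
        log.warning("inverted theoretical bounds C=%d > D=%d; "
                    "locus unfilterable by length", C, D)
        exemptions.add(Exemption.INSUFFICIENT_READS)
        return SupportingLengthStats(0, 0, C, D, E, {}, float("nan"), exemptions)

    clamped = []
    for v in support_values:
        if not C <= v <= D:
            log.debug("observed supporting length %d outside [%d, %d]; clamped",
                      v, C, D)
        clamped.append(min(max(v, C), D))
    A, B = min(clamped), max(clamped)

    f = null_distribution(null_values)
    used_fallback = False
    if _band_sum(f, C, D) == 0:
        log.info("null distribution empty on [%d, %d]; uniform fallback", C, D)
        f = {x: 1 for x in range(C, D + 1)}
        used_fallback = True
    p = multinomial_p(f, A, B, C, D, E)

    if (B - A + 1) > exemption_fraction * (D - C + 1):
        exemptions.add(Exemption.RANGE_75PCT)
    if _band_sum(f, A, B) > exemption_fraction * _band_sum(f, C, D):
        exemptions.add(Exemption.MASS_75PCT)

    return SupportingLengthStats(A, B, C, D, E, f, p, exemptions, used_fallback)


def apply_length_filter(stats: SupportingLengthStats,
                        p_threshold: float = 1e-6) -> bool:
    """Flag iff p < threshold (strict) and no exemption holds."""
    blocking = {Exemption.RANGE_75PCT, Exemption.MASS_75PCT,
                Exemption.INSUFFICIENT_READS}
    if stats.exemptions & blocking:
        return False
    return stats.p == stats.p and stats.p < p_threshold
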