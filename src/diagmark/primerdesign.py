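"""Allele-specific primer-trio design for diagnostic variants.

For each diagnostic variant three primers are designed: a species-positive
forward whose 3' end sits exactly on the diagnostic allele, a
species-negative forward identical except for the diagnostic base(s)
replaced by the non-target allele, and a common reverse primer placed in a
window that is conserved across all species' aligned reads (slid further
along the contig when no conserved window exists near the fragment).

In single-nucleotide mode the penultimate 3' base of both forwards is
additionally substituted to be non-complementary to every observed template
allele at that position (the ARMS principle): the target template then sees
a single, tolerated mismatch while any non-target template sees two
3'-terminal mismatches, which abolishes extension.  In dinucleotide mode
the two terminal bases already guarantee the double mismatch and no
artificial modification is made.

Melting temperatures use nearest-neighbor thermodynamics (unified
parameters, 50 mM monovalent salt, 250 nM primer) via Biopython, with the
Wallace rule available as a cross-check; annealing temperature is reported
as the trio's mean Tm minus 3 degC.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from Bio.SeqUtils import MeltingTemp as _mt

from ._sequtil import BASES, PURINES, complement, revcomp
from .diagvar import DiagnosticVariant
from .refmap import Pileup


class DesignError(ValueError):
    """Raised when no primer trio satisfies the constraints; the message
    carries a diagnosis of which constraint failed."""


@dataclass(frozen=True)
class DesignConstraints:
    primer_len_min: int = 18
    primer_len_max: int = 25
    amplicon_min: int = 100
    amplicon_max: int = 300
    tm_method: str = "nn"
    tm_target: float = 60.0
    annealing_offset: float = 3.0
    max_candidates: int = 10

    def __post_init__(self) -> None:
        if self.primer_len_min > self.primer_len_max:
            raise ValueError("empty primer length range")
        if self.amplicon_min > self.amplicon_max:
            raise ValueError("empty amplicon length range")


@dataclass(frozen=True)
class PrimerTrio:
    """Positive/negative forward pair plus common reverse, 5'->3'."""

    name: str
    positive: str
    negative: str
    common: str
    contig: str
    variant: DiagnosticVariant
    amplicon_positive: int
    amplicon_negative: int
    annealing_c: float
    tm_positive: float
    tm_negative: float
    tm_common: float
    dinucleotide_anchored: bool
    penultimate_modified: bool
    reverse_in_conserved_region: bool
    forward_start: int = 0  # 0-based contig coordinate of the forwards' 5' end
    reverse_window: tuple[int, int] = (0, 0)  # plus-strand span of the reverse site


def melting_temperature(sequence: str, method: str = "nn") -> float:
    """Primer melting temperature in degC.

    ``nn``: nearest-neighbor thermodynamics, unified parameters, 50 mM
    monovalent salt, 250 nM primer.  ``wallace``: the 4x(G+C) + 2x(A+T)
    rule of thumb.  Ambiguity codes are rejected.
    """
    if len(sequence) < 8:
        raise ValueError("sequence must be at least 8 nt")
    if any(b not in BASES for b in sequence.upper()):
        raise ValueError("ambiguity codes are not allowed in primers")
    if method == "nn":
        return float(_mt.Tm_NN(sequence, Na=50, dnac1=250, dnac2=0))
    if method == "wallace":
        return float(_mt.Tm_Wallace(sequence))
    raise ValueError(f"unknown Tm method {method!r}")


# ---------------------------------------------------------------------------
# conserved-window analysis
# ---------------------------------------------------------------------------


def _conserved_mask(contig: str, seq: str, pileup: Pileup | None) -> list[bool]:
    """Position-wise conservation: True where no species' aligned reads show
    any allele other than the reference base (uncovered positions count as
    conserved — nothing observed segregates there)."""
    mask = [True] * len(seq)
    if pileup is None:
        return mask
    for pos in pileup.positions(contig):
        col = pileup.column(contig, pos)
        for sp, counts in col.items():
            if any(b != seq[pos] for b in counts):
                mask[pos] = False
                break
    return mask


# ---------------------------------------------------------------------------
# trio design
# ---------------------------------------------------------------------------


def _penultimate_substitute(observed: set[str], current: str) -> str:
    """Pick the modified penultimate base: non-complementary to (i.e. a
    mismatch against) every observed template allele, preferring the
    purine-purine mismatch pairing that destabilizes most; ties break by
    fixed base order A<C<G<T."""
    candidates = [b for b in BASES if b not in observed and b != current]
    if not candidates:
        candidates = [b for b in BASES if b not in observed]
    if not candidates:
        raise DesignError(
            "all four bases occur at the penultimate position; "
            "cannot place a universal mismatch"
        )

    def destab(b: str) -> int:
        # mismatch pair is primer base vs the minus-strand template base
        return sum(b in PURINES and complement(t) in PURINES for t in observed)

    return max(candidates, key=lambda b: (destab(b), -BASES.index(b)))


def design_trio(
    contig: str,
    contig_seq: str,
    variant: DiagnosticVariant,
    pileup: Pileup | None,
    constraints: DesignConstraints = DesignConstraints(),
    name: str | None = None,
) -> list[PrimerTrio]:
    """Ranked candidate primer trios for one diagnostic variant.

    Forwards are built on the plus strand ending exactly on the variant;
    the common reverse is placed in a conserved window downstream such that
    the amplicon (distance between forward and reverse 5' ends, inclusive)
    lies in the configured range.  Candidates are ranked by the trio's worst
    |Tm - target|, then by a G/C 3'-end preference on the reverse, then by
    amplicon length.
    """
    c = constraints
    span = variant.span
    f_end = variant.end  # exclusive
    if f_end - c.primer_len_min < 0:
        raise DesignError(
            f"variant at {contig}:{variant.start} leaves no room for a "
            f"forward primer of length >= {c.primer_len_min}"
        )
    dinuc = span == 2
    mask = _conserved_mask(contig, contig_seq, pileup)

    # observed alleles at the penultimate position (single-nt mode)
    pen_pos = variant.start - 1
    observed = {contig_seq[pen_pos]}
    if pileup is not None:
        for counts in pileup.column(contig, pen_pos).values():
            observed.update(counts)
    pen_base = None if dinuc else _penultimate_substitute(
        observed, contig_seq[pen_pos])

    forwards: list[tuple[str, str, int]] = []  # (positive, negative, f_start)
    for lf in range(c.primer_len_min, c.primer_len_max + 1):
        f_start = f_end - lf
        if f_start < 0:
            continue
        core = list(contig_seq[f_start:f_end])
        pos_p = core.copy()
        pos_p[-span:] = variant.target_allele
        neg_p = core.copy()
        neg_p[-span:] = variant.non_target_allele
        if not dinuc:
            pos_p[-2] = pen_base
            neg_p[-2] = pen_base
        forwards.append(("".join(pos_p), "".join(neg_p), f_start))

    # reverse candidates: plus-strand windows [s, s+lr) fully conserved,
    # 3' of the variant, amplicon length within range for some forward.
    trios: list[tuple[tuple, PrimerTrio]] = []
    any_window = False
    base_name = name or f"{contig}:{variant.start + 1}"
    tm_cache: dict[str, float] = {}

    def _tm(seq: str) -> float:
        if seq not in tm_cache:
            tm_cache[seq] = melting_temperature(seq, c.tm_method)
        return tm_cache[seq]

    for (pos_seq, neg_seq, f_start), lr in itertools.product(
            forwards, range(c.primer_len_min, c.primer_len_max + 1)):
        lo = f_start + c.amplicon_min - lr
        hi = f_start + c.amplicon_max - lr
        for s in range(max(lo, f_end), hi + 1):
            if s + lr > len(contig_seq):
                break
            if not all(mask[s:s + lr]):
                continue
            any_window = True
            amplicon = s + lr - f_start
            common = revcomp(contig_seq[s:s + lr])
            try:
                tm_p = _tm(pos_seq)
                tm_n = _tm(neg_seq)
                tm_c = _tm(common)
            except ValueError:
                continue
            worst = max(abs(t - c.tm_target) for t in (tm_p, tm_n, tm_c))
            gc3 = common[-1] in "GC"
            anneal = round(
                (tm_p + tm_n + tm_c) / 3.0 - c.annealing_offset, 1)
            trio = PrimerTrio(
                base_name, pos_seq, neg_seq, common, contig, variant,
                amplicon, amplicon, anneal, tm_p, tm_n, tm_c,
                dinucleotide_anchored=dinuc,
                penultimate_modified=not dinuc,
                reverse_in_conserved_region=True,
                forward_start=f_start,
                reverse_window=(s, s + lr),
            )
            trios.append(((worst, not gc3, amplicon, lr), trio))
    if not trios:
        if not any_window:
            raise DesignError(
                f"no conserved reverse-primer window within the amplicon "
                f"range {c.amplicon_min}-{c.amplicon_max} bp downstream of "
                f"{contig}:{variant.start + 1}"
            )
        raise DesignError("no primer trio satisfies the Tm constraints")
    trios.sort(key=lambda t: t[0])
    return [t for _, t in trios[:c.max_candidates]]


# ---------------------------------------------------------------------------
# multiplex compatibility
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MultiplexReport:
    compatible: bool
    tolerance: float
    spread: float
    annealing: tuple[tuple[str, float], ...]
    pairwise_delta: tuple[tuple[str, str, float], ...] = field(default=())


def check_multiplex(
    trios: list[PrimerTrio],
    tolerance: float = 1.0,
    tm_method: str = "nn",
    annealing_offset: float = 3.0,
) -> MultiplexReport:
    """Can these trios run in one reaction mix?

    All primers' predicted annealing temperatures (Tm minus the annealing
    offset) must lie within ``tolerance`` of a common value; the report
    lists every pairwise delta-Tm.
    """
    if len(trios) < 2:
        raise ValueError("multiplex check needs at least 2 trios")
    temps: list[tuple[str, float]] = []
    for trio in trios:
        for role, seq in (("p", trio.positive), ("n", trio.negative),
                          ("uni", trio.common)):
            ta = melting_temperature(seq, tm_method) - annealing_offset
            temps.append((f"{trio.name}_{role}", round(ta, 2)))
    spread = max(t for _, t in temps) - min(t for _, t in temps)
    deltas = tuple(
        (a, b, round(abs(ta - tb), 2))
        for (a, ta), (b, tb) in itertools.combinations(temps, 2)
    )
    return MultiplexReport(
        compatible=spread / 2.0 <= tolerance,
        tolerance=tolerance,
        spread=round(spread, 2),
        annealing=tuple(temps),
        pairwise_delta=deltas,
    )
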