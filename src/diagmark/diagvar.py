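"""Species-diagnostic fixed-variant calling and hybrid screening.

A site is diagnostic for the target species when, at sufficient depth in
every species consulted, all target-species reads carry one allele that no
contrast-species read carries.  Two rule variants exist, distinguished by
the reference contig: the reference-carrying rule (the target allele is
also the reference base — the reference genome belongs to the target
species) and the reference-absent rule (the target allele is absent from
the reference).  Two adjacent diagnostic sites whose allele pairing is
read-phased merge into a single dinucleotide variant, preferred over its
two constituent single-site calls.

The calling model is deliberately combinatorial fixedness, not a genotype
likelihood: markers are scored as dominant presence/absence downstream, and
the discovery rule is "all reads of the target, no read of a contrast",
with an optional tolerance knob (default 0) for real-data error rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .refmap import Pileup

RULE_REF_CARRYING = "reference_carrying"
RULE_REF_ABSENT = "reference_absent"

SCREEN_PASS = "pass"
SCREEN_FAIL = "fail"
SCREEN_LOW_DEPTH = "insufficient_depth"


@dataclass(frozen=True)
class DiagnosticConfig:
    target_species: str
    contrast_species: tuple[str, ...]
    min_coverage: int = 32
    rule: str = "auto"  # reference_carrying | reference_absent | auto
    fixedness_tolerance: float = 0.0
    merge_dinucleotides: bool = True

    def __post_init__(self) -> None:
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")
        if not 0.0 <= self.fixedness_tolerance < 0.5:
            raise ValueError("fixedness_tolerance must be in [0, 0.5)")
        if self.rule not in ("auto", RULE_REF_CARRYING, RULE_REF_ABSENT):
            raise ValueError(f"unknown rule {self.rule!r}")


@dataclass(frozen=True)
class DiagnosticVariant:
    """A called diagnostic variant over a 1- or 2-base span."""

    contig: str
    start: int  # 0-based
    end: int    # half-open; end - start in {1, 2}
    target_allele: str
    non_target_allele: str
    target_species: str
    rule: str
    depths: tuple[tuple[str, int], ...] = field(default=())

    @property
    def span(self) -> int:
        return self.end - self.start

    def depth_of(self, species: str) -> int:
        return dict(self.depths).get(species, 0)


def _fixed_allele(
    counts: dict[str, int], tolerance: float
) -> tuple[str, int] | None:
    """Majority allele if discordant fraction <= tolerance; (allele, depth)."""
    depth = sum(counts.values())
    if depth == 0:
        return None
    allele = max(sorted(counts), key=counts.get)
    if (depth - counts[allele]) / depth > tolerance:
        return None
    return allele, depth


def _call_span(
    counts_by_species: dict[str, dict[str, int]],
    ref_allele: str | None,
    config: DiagnosticConfig,
) -> tuple[str, str, dict[str, int], str] | None:
    """Apply the fixedness rule at one span.

    Returns (target_allele, non_target_allele, depths, rule) or None.
    """
    tol = config.fixedness_tolerance
    tgt = counts_by_species.get(config.target_species, {})
    fixed = _fixed_allele(tgt, tol)
    if fixed is None:
        return None
    allele, tgt_depth = fixed
    if tgt_depth < config.min_coverage:
        return None
    depths = {config.target_species: tgt_depth}
    pooled: dict[str, int] = {}
    for sp in config.contrast_species:
        cnt = counts_by_species.get(sp, {})
        depth = sum(cnt.values())
        if depth < config.min_coverage:
            return None
        if cnt.get(allele, 0) / depth > tol:
            return None
        depths[sp] = depth
        for b, n in cnt.items():
            pooled[b] = pooled.get(b, 0) + n
    pooled.pop(allele, None)
    if not pooled:
        return None
    non_target = max(sorted(pooled), key=pooled.get)
    if ref_allele is None:
        return None
    rule = RULE_REF_CARRYING if allele == ref_allele else RULE_REF_ABSENT
    if config.rule != "auto" and rule != config.rule:
        return None
    return allele, non_target, depths, rule


def call_diagnostics(
    pileup: Pileup,
    config: DiagnosticConfig,
) -> list[DiagnosticVariant]:
    """Call every diagnostic site (and merged dinucleotide span) in a pileup.

    Output is sorted by contig then position; when two adjacent single-site
    calls are read-phased into a consistent dinucleotide (at full coverage
    and the same fixedness conditions on pair counts), the merged
    dinucleotide variant replaces them.
    """
    known = set(pileup.species)
    for sp in (config.target_species, *config.contrast_species):
        if sp not in known:
            raise ValueError(f"species {sp!r} absent from pileup")
    if not pileup.columns:
        raise ValueError("empty pileup")

    singles: dict[tuple[str, int], DiagnosticVariant] = {}
    for contig in pileup.contigs():
        for pos in pileup.positions(contig):
            res = _call_span(pileup.column(contig, pos),
                             pileup.ref_base(contig, pos), config)
            if res is None:
                continue
            allele, non_target, depths, rule = res
            singles[(contig, pos)] = DiagnosticVariant(
                contig, pos, pos + 1, allele, non_target,
                config.target_species, rule, tuple(sorted(depths.items())),
            )

    out: list[DiagnosticVariant] = []
    consumed: set[tuple[str, int]] = set()
    for (contig, pos) in sorted(singles):
        if (contig, pos) in consumed:
            continue
        nxt = (contig, pos + 1)
        if config.merge_dinucleotides and nxt in singles:
            res = _call_span(pileup.pair_counts(contig, pos),
                             pileup.ref_base(contig, pos, span=2), config)
            if res is not None:
                allele, non_target, depths, rule = res
                out.append(DiagnosticVariant(
                    contig, pos, pos + 2, allele, non_target,
                    config.target_species, rule,
                    tuple(sorted(depths.items())),
                ))
                consumed.add(nxt)
                continue
        out.append(singles[(contig, pos)])
    out.sort(key=lambda v: (v.contig, v.start))
    return out


def screen_in_hybrid(
    variants: list[DiagnosticVariant],
    hybrid_pileup: Pileup,
    hybrid_species: str,
    min_each_allele: int = 1,
) -> dict[DiagnosticVariant, str]:
    """Check that an F1 hybrid read set shows both alleles of each variant.

    A variant passes iff the hybrid shows at least ``min_each_allele`` reads
    of the target allele and of the non-target allele at the span; spans
    with total depth below twice that are reported as insufficient depth.
    """
    verdicts: dict[DiagnosticVariant, str] = {}
    for v in variants:
        if v.span == 1:
            counts = hybrid_pileup.column(v.contig, v.start).get(
                hybrid_species, {})
        else:
            counts = hybrid_pileup.pair_counts(v.contig, v.start).get(
                hybrid_species, {})
        depth = sum(counts.values())
        if depth < 2 * min_each_allele:
            verdicts[v] = SCREEN_LOW_DEPTH
        elif (counts.get(v.target_allele, 0) >= min_each_allele
              and counts.get(v.non_target_allele, 0) >= min_each_allele):
            verdicts[v] = SCREEN_PASS
        else:
            verdicts[v] = SCREEN_FAIL
    return verdicts


def detection_capability(carrier_count: int, total: int) -> float:
    """Percent of non-target individuals whose negative-primer site is
    intact, i.e. in which the species-negative assay amplifies — the
    hybrid-detection capability against that species.  One decimal place.
    """
    if total <= 0:
        raise ValueError("total must be > 0")
    if not 0 <= carrier_count <= total:
        raise ValueError("carrier_count must be within [0, total]")
    return round(100.0 * carrier_count / total, 1)
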