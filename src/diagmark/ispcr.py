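"""In-silico PCR with 3'-mismatch binding rules, and band-pattern
classification of samples into pure species / hybrid / other calls.

The binding rule operationalizes allele-specific (ARMS-style) priming as
read from gel outcomes: a primer site binds iff the 3'-terminal base
matches, at most one mismatch falls within the terminal two-base window,
and at most two mismatches occur overall.  A deliberately modified
penultimate base alone (one window mismatch) therefore still primes, while
terminal-plus-penultimate (two window mismatches, as seen by a positive
primer on a non-target template) abolishes amplification.  Markers are
dominant: on a diploid genotype, amplification from either haplotype gives
a band.

The decision table converts the four-assay presence/absence vector
(species-1 positive/negative, species-2 positive/negative) into an
identification call, including the partial-diagnostic caveat for species
whose negative-primer site segregates (the A. stellatus-type case) and the
maternal-parent caveat attached to every hybrid verdict.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from ._sequtil import revcomp, seq_to_array
from .simdata import IndividualGenome

# ---------------------------------------------------------------------------
# binding rule and site search
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BindingRule:
    terminal_window: int = 2
    max_window_mismatches: int = 1
    terminal_base_must_match: bool = True
    max_total_mismatches: int = 2
    max_product: int = 1500

    def __post_init__(self) -> None:
        if self.terminal_window < 1:
            raise ValueError("terminal_window must be >= 1")
        if min(self.max_window_mismatches, self.max_total_mismatches,
               self.max_product) < 0:
            raise ValueError("rule thresholds must be non-negative")


@dataclass(frozen=True)
class BindingSite:
    """A primer annealing site on a duplex template.

    ``kind`` 'fwd': the primer sequence matches the plus strand at
    [start, start+len) and extension runs rightward (3' end at ``end - 1``).
    ``kind`` 'rev': the primer anneals to the plus strand (its reverse
    complement matches at [start, start+len)) and extension runs leftward
    (3' end at ``start``).
    """

    kind: str
    start: int
    end: int
    mismatches: int


def _mismatch_profile(primer_arr: np.ndarray, tpl_arr: np.ndarray):
    L, n = len(primer_arr), len(tpl_arr)
    if L > n:
        return None
    width = n - L + 1
    total = np.zeros(width, dtype=np.int32)
    per_k = []
    for k in range(L):
        neq = tpl_arr[k:k + width] != primer_arr[k]
        total += neq
        per_k.append(neq)
    return total, per_k


def find_binding_sites(
    primer: str,
    template: str,
    rule: BindingRule = BindingRule(),
) -> list[BindingSite]:
    """All rule-satisfying annealing sites of one primer on one template."""
    if len(primer) > len(template):
        raise ValueError("primer longer than template")
    tpl = seq_to_array(template)
    L = len(primer)
    w = min(rule.terminal_window, L)
    sites: list[BindingSite] = []
    for kind, probe in (("fwd", primer), ("rev", revcomp(primer))):
        prof = _mismatch_profile(seq_to_array(probe), tpl)
        if prof is None:
            continue
        total, per_k = prof
        # primer 3'-terminal base index within the probe
        if kind == "fwd":
            window_ks = range(L - w, L)
            term_k = L - 1
        else:
            window_ks = range(0, w)
            term_k = 0
        wsum = np.zeros_like(total)
        for k in window_ks:
            wsum += per_k[k]
        ok = (total <= rule.max_total_mismatches) & \
             (wsum <= rule.max_window_mismatches)
        if rule.terminal_base_must_match:
            ok &= ~per_k[term_k]
        for i in np.nonzero(ok)[0]:
            sites.append(BindingSite(kind, int(i), int(i) + L, int(total[i])))
    return sites


def bind_and_amplify(
    forward_primer: str,
    reverse_primer: str,
    template: str,
    rule: BindingRule = BindingRule(),
) -> tuple[bool, list[int]]:
    """Predict amplification of a primer pair on one duplex template.

    Both primers are searched on both strands; a product forms when a
    forward-type site and a reverse-type site face each other within
    ``max_product``.  Product size is the span between the two primers' 5'
    ends, inclusive.
    """
    sites: list[tuple[BindingSite, int]] = []
    for p in dict.fromkeys((forward_primer, reverse_primer)):
        for s in find_binding_sites(p, template, rule):
            sites.append((s, len(p)))
    fwd = [s for s, _ in sites if s.kind == "fwd"]
    rev = [s for s, _ in sites if s.kind == "rev"]
    sizes: set[int] = set()
    for f in fwd:
        for r in rev:
            if f.start > r.start or f.end > r.end:
                continue
            size = r.end - f.start
            if size <= rule.max_product:
                sizes.add(size)
    return bool(sizes), sorted(sizes)


def amplify_genotype(
    forward_primer: str,
    reverse_primer: str,
    templates: Iterable[str],
    rule: BindingRule = BindingRule(),
) -> tuple[bool, list[int]]:
    """Dominant-marker amplification over a genotype's haplotype templates."""
    sizes: set[int] = set()
    for tpl in templates:
        _, s = bind_and_amplify(forward_primer, reverse_primer, tpl, rule)
        sizes.update(s)
    return bool(sizes), sorted(sizes)


# ---------------------------------------------------------------------------
# assay panel
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PanelAssay:
    """One locus of the panel: an allele-specific forward pair sharing a
    common reverse, yielding two band assays (positive, negative)."""

    name: str
    target_species: str
    positive_name: str
    positive: str
    negative_name: str
    negative: str
    common_name: str
    common: str
    product_bp: int


@dataclass(frozen=True)
class PanelConfig:
    """The assay panel: one locus per target species (species 1 first),
    plus verbatim protocol metadata carried into reports."""

    assays: tuple[PanelAssay, ...]
    protocol: tuple[tuple[str, str], ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.assays) < 1:
            raise ValueError("panel needs at least one assay")

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(a.target_species for a in self.assays)

    def band_ids(self) -> list[str]:
        out = []
        for a in self.assays:
            out += [a.positive_name, a.negative_name]
        return out


@dataclass(frozen=True)
class BandPattern:
    """Per-assay presence/absence for one sample; sizes only for present
    bands."""

    sample_id: str
    bands: dict[str, bool]
    sizes: dict[str, int | None]
    flags: tuple[str, ...] = ()

    def key(self, panel: PanelConfig) -> tuple[bool, ...]:
        return tuple(self.bands[b] for b in panel.band_ids())


def templates_of(genome: IndividualGenome) -> list[str]:
    out: list[str] = []
    for cid in sorted(genome.copies):
        out.extend(genome.copies[cid])
    return out


def run_panel(
    individuals: Sequence[IndividualGenome] | dict[str, Sequence[str]],
    panel: PanelConfig,
    rule: BindingRule = BindingRule(),
) -> list[BandPattern]:
    """Run every assay of the panel on every sample's haplotype templates."""
    if isinstance(individuals, dict):
        items = [(sid, list(tpls)) for sid, tpls in individuals.items()]
    else:
        items = [(g.sample_id, templates_of(g)) for g in individuals]
    patterns: list[BandPattern] = []
    for sid, templates in items:
        bands: dict[str, bool] = {}
        sizes: dict[str, int | None] = {}
        flags: list[str] = []
        if not templates:
            flags.append("assay_failure")
        for assay in panel.assays:
            for band_id, fwd in ((assay.positive_name, assay.positive),
                                 (assay.negative_name, assay.negative)):
                if templates:
                    present, szs = amplify_genotype(
                        fwd, assay.common, templates, rule)
                else:
                    present, szs = False, []
                bands[band_id] = present
                sizes[band_id] = szs[0] if present else None
        patterns.append(BandPattern(sid, bands, sizes, tuple(flags)))
    return patterns


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

VERDICT_PURE_1 = "pure_species_1"
VERDICT_PURE_2 = "pure_species_2"
VERDICT_F1 = "f1_hybrid_of_targets"
VERDICT_HYBRID_1_OTHER = "species_1_x_other_hybrid"
VERDICT_HYBRID_2_OTHER = "species_2_x_other_hybrid"
VERDICT_OTHER = "other_species"
VERDICT_OTHER_NEG_ABSENT = "other_species_negative_site_absent"
VERDICT_ASSAY_FAILURE = "assay_failure"
VERDICT_INCONCLUSIVE = "inconclusive"

CAVEAT_MATERNAL = "maternal parent undetermined"


@dataclass(frozen=True)
class IdentificationCall:
    sample_id: str
    verdict: str
    species_1: str
    species_2: str
    evidence: tuple[tuple[str, bool], ...]
    caveats: tuple[str, ...] = ()


def classify(pattern: BandPattern, panel: PanelConfig) -> IdentificationCall:
    """Decision table over the four-assay band pattern.

    Total over the 16 patterns: pure species-1 (+,-,-,+), pure species-2
    (-,+,+,-), any P1+ and P2+ is an F1 of the two targets (all four bands
    for a true F1), P+ together with the same species' N+ and the other
    species' P- is a hybrid of that species with an untyped other, both P-
    with both N+ is an other species, both P- with only N1+ is an other
    species whose species-2-negative site is absent (which cannot exclude a
    hybrid with species-2), all-negative is an assay failure, and anything
    else is inconclusive.  Hybrid verdicts always carry the
    maternal-parent-undetermined caveat.
    """
    if len(panel.assays) < 2:
        raise ValueError("classification needs a two-locus panel")
    a1, a2 = panel.assays[0], panel.assays[1]
    sp1, sp2 = a1.target_species, a2.target_species
    needed = [a1.positive_name, a1.negative_name,
              a2.positive_name, a2.negative_name]
    if any(b not in pattern.bands for b in needed):
        return IdentificationCall(
            pattern.sample_id, VERDICT_INCONCLUSIVE, sp1, sp2,
            tuple(pattern.bands.items()), ("missing assay in pattern",))
    p1, n1, p2, n2 = (pattern.bands[b] for b in needed)
    evidence = tuple(zip(needed, (p1, n1, p2, n2)))
    caveats: tuple[str, ...] = ()
    if p1 and not n1 and not p2 and n2:
        verdict = VERDICT_PURE_1
    elif not p1 and n1 and p2 and not n2:
        verdict = VERDICT_PURE_2
    elif p1 and p2:
        verdict = VERDICT_F1
        caveats = (CAVEAT_MATERNAL,)
    elif p1 and n1 and not p2:
        verdict = VERDICT_HYBRID_1_OTHER
        caveats = (CAVEAT_MATERNAL,)
    elif p2 and n2 and not p1:
        verdict = VERDICT_HYBRID_2_OTHER
        caveats = (CAVEAT_MATERNAL,)
    elif not p1 and not p2 and n1 and n2:
        verdict = VERDICT_OTHER
    elif not p1 and not p2 and n1 and not n2:
        verdict = VERDICT_OTHER_NEG_ABSENT
        caveats = (f"hybrid with {sp2} not excluded",)
    elif not any((p1, n1, p2, n2)):
        verdict = VERDICT_ASSAY_FAILURE
    else:
        verdict = VERDICT_INCONCLUSIVE
    return IdentificationCall(
        pattern.sample_id, verdict, sp1, sp2, evidence, caveats)
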