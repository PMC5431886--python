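"""Tests for diagnostic-variant calling, hybrid screening, and detection
capability."""

import pytest

from diagmark import (
    DiagnosticConfig,
    DiagnosticVariant,
    Pileup,
    call_diagnostics,
    detection_capability,
    screen_in_hybrid,
)
from diagmark.diagvar import (
    RULE_REF_ABSENT,
    RULE_REF_CARRYING,
    SCREEN_FAIL,
    SCREEN_LOW_DEPTH,
    SCREEN_PASS,
)

AR = "A_ruthenus"
HH = "H_huso"
AB = "A_baerii"


def dinuc_pileup(target_depth=36, ref="AG"):
    """Worked discovery pileup: target reads AG, contrasts CT, at depths
    36 / 39 / 78 over an AG-carrying reference span."""
    cols = {
        ("140238", 10): {AR: {"A": target_depth}, HH: {"C": 39}, AB: {"C": 78}},
        ("140238", 11): {AR: {"G": target_depth}, HH: {"T": 39}, AB: {"T": 78}},
    }
    pairs = {("140238", 10): {AR: {"AG": target_depth}, HH: {"CT": 39},
                              AB: {"CT": 78}}}
    return Pileup.from_counts(cols, {"140238": {10: ref[0], 11: ref[1]}}, pairs)


def single_pileup():
    """Worked single-nucleotide pileup: 509 target C, contrasts 484/740 G,
    reference G (reference-absent rule)."""
    cols = {("216845", 20): {HH: {"C": 509}, AR: {"G": 484}, AB: {"G": 740}}}
    return Pileup.from_counts(cols, {"216845": {20: "G"}})


def test_reference_carrying_dinucleotide_call():
    calls = call_diagnostics(dinuc_pileup(), DiagnosticConfig(AR, (HH, AB)))
    assert len(calls) == 1
    v = calls[0]
    assert (v.contig, v.start, v.end) == ("140238", 10, 12)
    assert (v.target_allele, v.non_target_allele) == ("AG", "CT")
    assert v.rule == RULE_REF_CARRYING
    assert v.depth_of(AR) == 36 and v.depth_of(AB) == 78


def test_reference_absent_single_call():
    calls = call_diagnostics(single_pileup(), DiagnosticConfig(HH, (AR, AB)))
    assert len(calls) == 1
    v = calls[0]
    assert (v.target_allele, v.non_target_allele) == ("C", "G")
    assert v.rule == RULE_REF_ABSENT
    assert v.span == 1


def test_depth_below_min_coverage_not_called():
    calls = call_diagnostics(dinuc_pileup(target_depth=31),
                             DiagnosticConfig(AR, (HH, AB)))
    assert calls == []
    # boundary: exactly 32 is called
    calls = call_diagnostics(dinuc_pileup(target_depth=32),
                             DiagnosticConfig(AR, (HH, AB)))
    assert len(calls) == 1


def test_rule_restriction_filters_calls():
    assert call_diagnostics(
        dinuc_pileup(), DiagnosticConfig(AR, (HH, AB), rule=RULE_REF_ABSENT)
    ) == []
    assert call_diagnostics(
        single_pileup(), DiagnosticConfig(HH, (AR, AB), rule=RULE_REF_ABSENT)
    ) != []


def test_unphased_adjacency_stays_two_single_calls():
    """Adjacent sites without read-phased pair support are not merged."""
    cols = {
        ("c", 10): {AR: {"A": 40}, HH: {"C": 40}, AB: {"C": 40}},
        ("c", 11): {AR: {"G": 40}, HH: {"T": 40}, AB: {"T": 40}},
    }
    pile = Pileup.from_counts(cols, {"c": {10: "A", 11: "G"}},
                              {("c", 10): {}})  # no read covers both
    calls = call_diagnostics(pile, DiagnosticConfig(AR, (HH, AB)))
    assert [v.span for v in calls] == [1, 1]


def test_contrast_carrying_target_allele_blocks_call():
    cols = {("c", 5): {AR: {"A": 40}, HH: {"A": 2, "C": 38}, AB: {"C": 40}}}
    pile = Pileup.from_counts(cols, {"c": {5: "A"}})
    assert call_diagnostics(pile, DiagnosticConfig(AR, (HH, AB))) == []
    # a tolerance of 0.1 forgives the two discordant contrast reads
    calls = call_diagnostics(
        pile, DiagnosticConfig(AR, (HH, AB), fixedness_tolerance=0.1))
    assert len(calls) == 1


def test_min_coverage_monotonicity(world):
    lo = call_diagnostics(world.pileup, DiagnosticConfig(
        AR, (HH, AB), min_coverage=32, merge_dinucleotides=False))
    hi = call_diagnostics(world.pileup, DiagnosticConfig(
        AR, (HH, AB), min_coverage=41, merge_dinucleotides=False))
    assert set(hi) <= set(lo)


def test_tolerance_monotonicity(world):
    tight = call_diagnostics(world.pileup, DiagnosticConfig(
        AR, (HH, AB), merge_dinucleotides=False))
    loose = call_diagnostics(world.pileup, DiagnosticConfig(
        AR, (HH, AB), fixedness_tolerance=0.2, merge_dinucleotides=False))
    assert {(v.contig, v.start) for v in tight} <= \
        {(v.contig, v.start) for v in loose}


def test_target_contrast_symmetry_yields_disjoint_sites(world):
    a = call_diagnostics(world.pileup, DiagnosticConfig(AR, (HH, AB)))
    b = call_diagnostics(world.pileup, DiagnosticConfig(HH, (AR, AB)))
    assert not ({(v.contig, v.start) for v in a}
                & {(v.contig, v.start) for v in b})


def test_unknown_species_and_empty_pileup_rejected():
    pile = single_pileup()
    with pytest.raises(ValueError, match="absent"):
        call_diagnostics(pile, DiagnosticConfig("nope", (AR,)))
    empty = Pileup.from_counts({}, {})
    with pytest.raises(ValueError):
        call_diagnostics(empty, DiagnosticConfig(HH, (AR,)))


def test_calls_match_naive_exhaustive_checker(world):
    """Single-site calls equal an independent per-position re-check of the
    fixedness rule on the same pileup."""
    config = DiagnosticConfig(HH, (AR, AB), merge_dinucleotides=False)
    got = {(v.contig, v.start, v.target_allele)
           for v in call_diagnostics(world.pileup, config)}
    want = set()
    for cid in world.pileup.contigs():
        for pos in world.pileup.positions(cid):
            col = world.pileup.column(cid, pos)
            tgt = col.get(HH, {})
            if len(tgt) != 1 or sum(tgt.values()) < 32:
                continue
            allele = next(iter(tgt))
            ok = True
            others = {}
            for sp in (AR, AB):
                cnt = col.get(sp, {})
                if sum(cnt.values()) < 32 or cnt.get(allele, 0) > 0:
                    ok = False
                    break
                others.update(cnt)
            if ok and others:
                want.add((cid, pos, allele))
    assert got == want


# ---------------------------------------------------------------------------
# hybrid screening
# ---------------------------------------------------------------------------


def _variant(span=1):
    if span == 1:
        return DiagnosticVariant("216845", 20, 21, "C", "G", HH,
                                 RULE_REF_ABSENT)
    return DiagnosticVariant("140238", 10, 12, "AG", "CT", AR,
                             RULE_REF_CARRYING)


def test_bester_screen_passes_at_printed_counts():
    pile = Pileup.from_counts(
        {("216845", 20): {"bester": {"C": 95, "G": 109}}},
        {"216845": {20: "G"}},
        {("140238", 10): {"bester": {"AG": 9, "CT": 7}}},
    )
    verdicts = screen_in_hybrid([_variant(1), _variant(2)], pile, "bester")
    assert set(verdicts.values()) == {SCREEN_PASS}


def test_single_allele_hybrid_fails_screen():
    pile = Pileup.from_counts(
        {("216845", 20): {"bester": {"C": 50}}}, {"216845": {20: "G"}})
    verdicts = screen_in_hybrid([_variant(1)], pile, "bester")
    assert list(verdicts.values()) == [SCREEN_FAIL]


def test_insufficient_depth_reported():
    pile = Pileup.from_counts(
        {("216845", 20): {"bester": {"C": 1}}}, {"216845": {20: "G"}})
    verdicts = screen_in_hybrid([_variant(1)], pile, "bester",
                                min_each_allele=1)
    assert list(verdicts.values()) == [SCREEN_LOW_DEPTH]


# ---------------------------------------------------------------------------
# detection capability
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("carriers,total,expect", [
    (23, 40, 57.5),
    (40, 40, 100.0),
    (0, 40, 0.0),
    (27, 40, 67.5),
])
def test_detection_capability(carriers, total, expect):
    assert detection_capability(carriers, total) == expect


def test_detection_capability_rejects_bad_inputs():
    with pytest.raises(ValueError):
        detection_capability(1, 0)
    with pytest.raises(ValueError):
        detection_capability(41, 40)
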