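"""Unit and property tests for the ddRAD simulation module."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from diagmark import (
    BSTYI,
    SPHI,
    EnzymeSpec,
    SizeSelectSpec,
    VariantSpec,
    digest_and_select,
    make_barcodes,
    make_ddrad_reference,
    make_individual,
    plant_variants,
    sequence_reads,
    simulate_reference,
)
from conftest import oracle_digest, rc


# ---------------------------------------------------------------------------
# reference simulation
# ---------------------------------------------------------------------------


def test_simulate_reference_deterministic_and_seed_sensitive():
    a = simulate_reference(1, 500, 0.5, seed=7)
    b = simulate_reference(1, 500, 0.5, seed=7)
    c = simulate_reference(2, 1000, 0.5, seed=7)
    d = simulate_reference(2, 1000, 0.5, seed=8)
    assert a == b
    assert list(c.values()) != list(d.values())


def test_simulate_reference_gc_fraction_tracks_request():
    seq = simulate_reference(1, 100_000, 0.4, seed=3)["140238"]
    gc = (seq.count("G") + seq.count("C")) / len(seq)
    assert abs(gc - 0.4) <= 0.02


@pytest.mark.parametrize("bad", [
    dict(n_contigs=0, contig_length=500),
    dict(n_contigs=1, contig_length=100),
    dict(n_contigs=1, contig_length=500, gc_fraction=1.5),
])
def test_simulate_reference_rejects_bad_sizes(bad):
    with pytest.raises(ValueError):
        simulate_reference(**{"gc_fraction": 0.5, "seed": 0, **bad})


def test_enzyme_spec_invariants():
    with pytest.raises(ValueError):
        EnzymeSpec("bad", "GCATGX", 1)
    with pytest.raises(ValueError):
        EnzymeSpec("bad", "GCATGC", 7)
    assert SPHI.residual == "CATGC"
    assert BSTYI.residual == "GATCY"


# ---------------------------------------------------------------------------
# digestion and size selection
# ---------------------------------------------------------------------------


def _spaced_template(insert: int) -> str:
    """SphI site ... BstYI site with a chosen duplex fragment length."""
    rng = np.random.default_rng(5)
    pad = "".join(rng.choice(list("ACGT"), size=60))
    # duplex fragment runs from sphi_pos+1 to bstyi_pos+5
    mid_len = insert - 4 - len(BSTYI.recognition)
    mid = "".join(rng.choice(list("ACGT"), size=mid_len))
    return pad + "GCATGC" + mid + "AGATCT" + pad


def test_mixed_end_fragment_in_window_is_retained():
    # insert chosen so fragment + 80 adapter = 400
    tpl = {"c": _spaced_template(320)}
    frags = digest_and_select(tpl)
    assert len(frags) == 1
    assert frags[0].length + 80 == 400
    assert frags[0].strand == "+"
    assert frags[0].seq.startswith("CATGC")
    assert rc(frags[0].seq).startswith("GATCY".replace("Y", "T"))


def test_same_enzyme_ends_are_excluded():
    rng = np.random.default_rng(6)
    pad = "".join(rng.choice(list("ACGT"), size=40))
    mid = "".join(rng.choice(list("ACGT"), size=330))
    tpl = {"c": pad + "GCATGC" + mid + "GCATGC" + pad}
    assert digest_and_select(tpl) == []


def test_retained_lengths_respect_adapter_inclusive_window():
    ref = simulate_reference(10, 5000, 0.5, seed=9)
    spec = SizeSelectSpec()
    for f in digest_and_select(ref, size_spec=spec):
        assert spec.min_len <= f.length + spec.adapter_extra <= spec.max_len


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.data())
def test_digestion_matches_naive_all_positions_oracle(data):
    """Fragment boundaries equal those of an exhaustive IUPAC scan."""
    rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
    seq = list("".join(rng.choice(list("ACGT"), size=1200)))
    for _ in range(data.draw(st.integers(0, 6))):
        pos = data.draw(st.integers(0, len(seq) - 7))
        site = data.draw(st.sampled_from(["GCATGC", "AGATCT", "GGATCC"]))
        seq[pos:pos + 6] = site
    s = "".join(seq)
    spec = SizeSelectSpec(10, 2000, 0)  # wide window: test boundary logic
    got = {(f.start, f.end) for f in digest_and_select({"c": s}, size_spec=spec)}
    want = {(a, b) for a, b, _, _ in oracle_digest(s, SPHI, BSTYI, spec)}
    assert got == want


def test_engineered_reference_yields_one_fragment_per_contig():
    ref, loci = make_ddrad_reference(5, seed=4)
    frags = digest_and_select(ref)
    assert len(frags) == 5
    by_contig = {f.contig: f for f in frags}
    for lo in loci:
        f = by_contig[lo.contig]
        assert (f.start, f.end) == (lo.frag_start, lo.frag_end)


# ---------------------------------------------------------------------------
# variant planting and individuals
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def small_models():
    ref, loci = make_ddrad_reference(2, seed=21)
    pos = loci[0].variant_window[0]
    pos2 = loci[1].variant_window[0]
    variants = [
        VariantSpec(loci[0].contig, pos, "AG", "A"),
        VariantSpec(loci[0].contig, pos, "CT", "B"),
        VariantSpec(loci[0].contig, pos, "CT", "C"),
        VariantSpec(loci[1].contig, pos2, "C", "B"),
        VariantSpec(loci[1].contig, pos2, "G", "A"),
        VariantSpec(loci[1].contig, pos2, "G", "C"),
        # partially-segregating site in species C, third allele background
        VariantSpec(loci[0].contig, pos, "CT", "D", fixedness=23 / 40,
                    noncarrier_allele="CC"),
    ]
    models = plant_variants(ref, ["A", "B", "C", "D"], variants)
    return ref, loci, models, (pos, pos2)


def test_planted_fixed_variants_are_species_exclusive(small_models):
    ref, loci, models, (pos, _) = small_models
    cid = loci[0].contig
    assert models["A"].haplotypes[cid][pos:pos + 2] == "AG"
    assert models["B"].haplotypes[cid][pos:pos + 2] == "CT"
    assert models["C"].haplotypes[cid][pos:pos + 2] == "CT"


def test_empty_specs_leave_haplotypes_identical_to_reference():
    ref, _ = make_ddrad_reference(2, seed=22)
    models = plant_variants(ref, ["X"], [])
    assert models["X"].haplotypes == ref


def test_overlapping_spans_and_site_overlap_are_rejected():
    ref, loci = make_ddrad_reference(1, seed=23)
    cid = loci[0].contig
    pos = loci[0].variant_window[0]
    with pytest.raises(ValueError, match="overlapping"):
        plant_variants(ref, ["A"], [
            VariantSpec(cid, pos, "AG", "A"),
            VariantSpec(cid, pos + 1, "C", "A"),
        ])
    # the engineered SphI site starts at frag_start - 5
    with pytest.raises(ValueError, match="restriction"):
        plant_variants(ref, ["A"], [
            VariantSpec(cid, loci[0].frag_start - 1, "A", "A")])


def test_partial_fixedness_realizes_expected_carrier_fraction(small_models):
    ref, loci, models, (pos, _) = small_models
    cid = loci[0].contig
    carriers = 0
    for i in range(40):
        ind = make_individual("D", models, seed=1000 + i)
        if ind.copies[cid][0][pos:pos + 2] == "CT":
            carriers += 1
        else:
            assert ind.copies[cid][0][pos:pos + 2] == "CC"
    # Binomial(40, 23/40): mean 23, 3 sigma ~ 9.4
    assert abs(carriers - 23) <= 10


def test_pure_individual_is_homozygous_at_diagnostic_sites(small_models):
    _, loci, models, (pos, pos2) = small_models
    ind = make_individual("B", models, seed=1)
    assert ind.copies[loci[1].contig][0][pos2] == "C"
    assert ind.copies[loci[1].contig][1][pos2] == "C"
    het = sum(a != b for a, b in zip(*ind.copies[loci[1].contig]))
    assert het == 0


def test_f1_is_heterozygous_at_every_fixed_differential_site(small_models):
    _, loci, models, (pos, pos2) = small_models
    f1 = make_individual(("B", "A"), models, seed=2)
    c0, c1 = f1.copies[loci[1].contig]
    assert {c0[pos2], c1[pos2]} == {"C", "G"}
    c0, c1 = f1.copies[loci[0].contig]
    assert {c0[pos:pos + 2], c1[pos:pos + 2]} == {"CT", "AG"}


def test_unknown_species_rejected(small_models):
    _, _, models, _ = small_models
    with pytest.raises(ValueError, match="unknown species"):
        make_individual("nope", models, seed=0)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def read_world(small_models):
    _, loci, models, _ = small_models
    ind = make_individual("A", models, seed=7, sample_id="s1")
    frags = digest_and_select(ind)
    barcodes = make_barcodes(["s1"], seed=7)
    pairs = sequence_reads({"s1": frags}, barcodes, coverage=5, seed=7)
    return ind, frags, barcodes, pairs


def test_read_geometry_and_zero_error_fidelity(read_world):
    ind, frags, barcodes, pairs = read_world
    by_id = {f.frag_id: f for f in frags}
    bc = barcodes["s1"]
    for p in pairs:
        assert len(p.read1) == len(p.read2) == 125
        src = by_id[p.fragment_id]
        assert p.read1 == bc + src.seq[:125 - len(bc)]
        assert p.read2 == rc(src.seq)[:125]
        assert p.read1[len(bc):].startswith("CATGC")


def test_reads_are_deterministic_for_fixed_seed(read_world):
    _, frags, barcodes, pairs = read_world
    again = sequence_reads({"s1": frags}, barcodes, coverage=5, seed=7)
    assert again == pairs


def test_allele_conservation_in_error_free_reads(small_models, read_world):
    """At a planted fixed site, error-free reads carry exactly the
    individual's genotype alleles."""
    _, loci, models, (pos, _) = small_models
    ind, frags, _, pairs = read_world
    cid = loci[0].contig
    offset = pos - loci[0].frag_start  # within read 1
    seen = set()
    for p in pairs:
        if p.fragment_id.startswith(f"{cid}:"):
            seen.add(p.read1[6 + offset:6 + offset + 2])
    geno = {ind.copies[cid][0][pos:pos + 2], ind.copies[cid][1][pos:pos + 2]}
    assert seen == geno


def test_f1_reads_contain_both_alleles(small_models):
    _, loci, models, (pos, _) = small_models
    f1 = make_individual(("B", "A"), models, seed=9, sample_id="f1")
    frags = digest_and_select(f1)
    barcodes = make_barcodes(["f1"], seed=9)
    pairs = sequence_reads({"f1": frags}, barcodes, coverage=2, seed=9)
    cid = loci[0].contig
    offset = pos - loci[0].frag_start
    seen = {p.read1[6 + offset:6 + offset + 2] for p in pairs
            if p.fragment_id.startswith(f"{cid}:")}
    assert seen == {"AG", "CT"}


def test_error_rate_is_calibrated(read_world):
    _, frags, barcodes, _ = read_world
    pairs = sequence_reads({"s1": frags}, barcodes, coverage=200,
                           error_rate=0.002, seed=13)
    by_id = {f.frag_id: f for f in frags}
    bc = barcodes["s1"]
    errs = bases = 0
    for p in pairs:
        src = by_id[p.fragment_id]
        t1 = bc + src.seq[:119]
        t2 = rc(src.seq)[:125]
        errs += sum(a != b for a, b in zip(p.read1, t1))
        errs += sum(a != b for a, b in zip(p.read2, t2))
        bases += 250
    assert bases >= 100_000
    mean = 0.002 * bases
    sigma = (bases * 0.002 * 0.998) ** 0.5
    assert abs(errs - mean) <= 3 * sigma


def test_close_barcodes_are_rejected(read_world):
    _, frags, _, _ = read_world
    with pytest.raises(ValueError, match="Hamming"):
        sequence_reads({"s1": frags}, {"s1": "AAAAAA", "s2": "AAAAAT"},
                       seed=0)


def test_generated_barcodes_satisfy_distance():
    codes = list(make_barcodes([f"s{i}" for i in range(8)], seed=3).values())
    for i in range(len(codes)):
        for j in range(i + 1, len(codes)):
            d = sum(a != b for a, b in zip(codes[i], codes[j]))
            assert d >= 3
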