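"""Shared fixtures and independent oracles for the test suite.

The oracles re-derive digestion and mapping semantics with naive
all-positions scans so the package's seed-and-extend / event-sorted
implementations can be checked against an implementation-independent
reference on small instances.
"""

from __future__ import annotations

import itertools
from types import SimpleNamespace

import pytest

from diagmark import (
    DiagnosticConfig,
    MappingConfig,
    ReadProcConfig,
    VariantSpec,
    build_pileup,
    call_diagnostics,
    digest_and_select,
    make_barcodes,
    make_ddrad_reference,
    make_individual,
    map_reads,
    plant_variants,
    preprocess,
    sequence_reads,
    update_reference,
)

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

_IUP = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R",
         "S": "S", "W": "W", "K": "M", "M": "K", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def oracle_digest(seq, enz_a, enz_b, size_spec):
    """Naive all-positions double-digest: every IUPAC match of either
    recognition pattern (both strands) is a cut event spanning the duplex
    extent min-cut..max-cut; mixed-enzyme neighbours within the
    adapter-inclusive window are the retained fragments."""

    def match(pat, i):
        return all(seq[i + j] in _IUP[p] for j, p in enumerate(pat))

    events = set()
    for enz in (enz_a, enz_b):
        lo_off = min(enz.cut_offset, len(enz.recognition) - enz.cut_offset)
        hi_off = max(enz.cut_offset, len(enz.recognition) - enz.cut_offset)
        for pat in {enz.recognition, rc(enz.recognition)}:
            for i in range(len(seq) - len(pat) + 1):
                if match(pat, i):
                    events.add((i + lo_off, i + hi_off, enz.name))
    ordered = sorted(events)
    frags = set()
    for (lo1, hi1, n1), (lo2, hi2, n2) in itertools.pairwise(ordered):
        if n1 == n2 or hi2 <= lo1:
            continue
        length = hi2 - lo1
        if size_spec.min_len <= length + size_spec.adapter_extra <= size_spec.max_len:
            frags.add((lo1, hi2, n1, n2))
    return frags


def oracle_map(read, contigs, config=MappingConfig()):
    """Exhaustive scoring of every (contig, start, strand) with at most one
    interior gap run of length <= max_gap_length; returns the mapper's
    expected outcome: ('mapped', contig, start, strand, score) or
    ('unmapped',)."""
    cost, gp = config.mismatch_cost, config.gap_penalty
    scores = {}
    for cid, ref in contigs.items():
        n = len(ref)
        for strand, s in (("+", read), ("-", rc(read))):
            L = len(s)
            for start in range(n - L + 1):
                best = None
                mm = sum(a != b for a, b in zip(s, ref[start:start + L]))
                best = (L - mm) - cost * mm
                for g in range(1, config.max_gap_length + 1):
                    if config.max_gaps < 1:
                        break
                    if start + L + g <= n:  # deletion from the read
                        for i in range(1, L):
                            mm = sum(a != b for a, b in zip(s[:i], ref[start:start + i]))
                            mm += sum(a != b for a, b in
                                      zip(s[i:], ref[start + i + g:start + L + g]))
                            sc = (L - mm) - cost * mm - gp
                            best = max(best, sc)
                    if L - g >= 2:  # insertion in the read
                        for i in range(1, L - g):
                            mm = sum(a != b for a, b in zip(s[:i], ref[start:start + i]))
                            mm += sum(a != b for a, b in
                                      zip(s[i + g:], ref[start + i:start + L - g]))
                            sc = (L - g - mm) - cost * mm - gp
                            best = max(best, sc)
                scores[(cid, start, strand)] = best
    if not scores:
        return ("unmapped",)
    top = max(scores.values())
    winners = [k for k, v in scores.items() if v == top]
    if len(winners) != 1:
        return ("unmapped",)
    cid, start, strand = winners[0]
    L = len(read)
    # identity acceptance mirrors the configured minimum aligned fraction:
    # rescore the winning placement to recover its match count
    ref = contigs[cid]
    s = read if strand == "+" else rc(read)
    Lr = len(s)
    cands = []
    mm = sum(a != b for a, b in zip(s, ref[start:start + Lr]))
    cands.append((Lr - mm - cost * mm, Lr - mm))
    for g in range(1, config.max_gap_length + 1):
        if start + Lr + g <= len(ref):
            for i in range(1, Lr):
                mm = sum(a != b for a, b in zip(s[:i], ref[start:start + i]))
                mm += sum(a != b for a, b in
                          zip(s[i:], ref[start + i + g:start + Lr + g]))
                cands.append(((Lr - mm) - cost * mm - gp, Lr - mm))
        if Lr - g >= 2:
            for i in range(1, Lr - g):
                mm = sum(a != b for a, b in zip(s[:i], ref[start:start + i]))
                mm += sum(a != b for a, b in
                          zip(s[i + g:], ref[start + i:start + Lr - g]))
                cands.append(((Lr - g - mm) - cost * mm - gp, Lr - g - mm))
    sc, matches = max(cands)
    if matches / L < config.min_fraction_aligned:
        return ("unmapped",)
    return ("mapped", cid, start, strand, top)


# ---------------------------------------------------------------------------
# end-to-end simulated world
# ---------------------------------------------------------------------------

SPECIES = ["A_ruthenus", "H_huso", "A_baerii"]
CROSS = ("H_huso", "A_ruthenus")


def build_world(n_contigs=20, n_dinuc=5, n_single=5, coverage=20,
                error_rate=0.0, seed=11):
    """Three species plus an F1 hybrid over engineered ddRAD contigs, with
    fixed dinucleotide diagnostics for the reference species and fixed
    single-nucleotide diagnostics for the second target; reads are
    preprocessed, mapped (majority-update pass on the reference species),
    and piled up per species."""
    reference, loci = make_ddrad_reference(n_contigs, seed=seed)
    variants = []
    planted = {"A_ruthenus": [], "H_huso": []}
    for i in range(n_dinuc):
        pos = loci[i].variant_window[0] + 10
        v = VariantSpec(loci[i].contig, pos, "AG", "A_ruthenus")
        planted["A_ruthenus"].append(v)
        variants += [v,
                     VariantSpec(loci[i].contig, pos, "CT", "H_huso"),
                     VariantSpec(loci[i].contig, pos, "CT", "A_baerii")]
    for i in range(n_dinuc, n_dinuc + n_single):
        pos = loci[i].variant_window[0] + 10
        v = VariantSpec(loci[i].contig, pos, "C", "H_huso")
        planted["H_huso"].append(v)
        variants += [v,
                     VariantSpec(loci[i].contig, pos, "G", "A_ruthenus"),
                     VariantSpec(loci[i].contig, pos, "G", "A_baerii")]
    models = plant_variants(reference, SPECIES, variants)
    map_reference = dict(models["A_ruthenus"].haplotypes)
    samples = {
        "ar1": "A_ruthenus",
        "hh1": "H_huso",
        "ab1": "A_baerii",
        "be1": CROSS,
    }
    genomes = {sid: make_individual(soc, models, seed=seed + i, sample_id=sid)
               for i, (sid, soc) in enumerate(samples.items())}
    barcodes = make_barcodes(sorted(samples), seed=seed)
    frags = {sid: digest_and_select(genomes[sid]) for sid in samples}
    pairs = sequence_reads(frags, barcodes, coverage=coverage,
                           error_rate=error_rate, seed=seed)
    by_sample, discards = preprocess(pairs, barcodes, ReadProcConfig())
    singles = {
        sid: [(f"{p.read_id}/1", p.read1) for p in sample_pairs]
             + [(f"{p.read_id}/2", p.read2) for p in sample_pairs]
        for sid, sample_pairs in by_sample.items()
    }
    config = MappingConfig()
    aln_ref, _ = map_reads(singles["ar1"], map_reference, config)
    updated, removed = update_reference(map_reference, aln_ref)
    by_species = {}
    unmapped = {}
    for sid, soc in samples.items():
        label = soc if isinstance(soc, str) else f"{soc[0]}x{soc[1]}"
        alns, unm = map_reads(singles[sid], updated, config)
        by_species.setdefault(label, []).extend(alns)
        unmapped[sid] = unm
    pileup = build_pileup(by_species, updated)
    return SimpleNamespace(
        reference=reference, map_reference=map_reference, loci=loci,
        models=models, genomes=genomes, samples=samples, barcodes=barcodes,
        fragments=frags, pairs=pairs, processed=by_sample, discards=discards,
        singles=singles, updated=updated, removed=removed,
        alignments_by_species=by_species, unmapped=unmapped, pileup=pileup,
        planted=planted, hybrid_label=f"{CROSS[0]}x{CROSS[1]}",
    )


@pytest.fixture(scope="session")
def world():
    return build_world()


@pytest.fixture(scope="session")
def called_variants(world):
    ar = call_diagnostics(world.pileup, DiagnosticConfig(
        "A_ruthenus", ("H_huso", "A_baerii")))
    hh = call_diagnostics(world.pileup, DiagnosticConfig(
        "H_huso", ("A_ruthenus", "A_baerii")))
    return {"A_ruthenus": ar, "H_huso": hh}
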