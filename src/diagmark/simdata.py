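"""Seeded simulation of ddRAD-style sequencing experiments.

The generator emulates the study design this package targets: several
sturgeon-like species sharing one ancestral contig set, with fixed
inter-species variants planted at known positions (single-nucleotide and
adjacent dinucleotide substitutions, plus partially-segregating sites in a
non-target species), diploid individuals and F1 hybrids, SphI+BstYI
double-digestion with 340-490 bp size selection (80 bp of that window being
adapter), and 125 bp barcoded paired-end reads with configurable
substitution error.

Every downstream stage of the pipeline (preprocessing, mapping, diagnostic
variant calling, primer design, in-silico PCR) is testable against this
module without any external data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from ._sequtil import (
    BASES,
    find_iupac,
    hamming,
    is_iupac,
    random_dna,
    revcomp,
)

# ---------------------------------------------------------------------------
# enzymes and size selection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnzymeSpec:
    """A type-II restriction enzyme with a palindromic recognition site.

    ``cut_offset`` is the top-strand cut position within the recognition
    match; the bottom-strand cut follows from palindromic symmetry at
    ``len(recognition) - cut_offset``.  Fragments retain the full duplex
    extent through the sticky end, so a read entering a fragment from a
    junction of this enzyme always starts with ``residual`` regardless of
    fragment orientation.
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not is_iupac(self.recognition):
            raise ValueError(f"recognition site {self.recognition!r} is not IUPAC")
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValueError("cut_offset outside recognition site")

    @property
    def cut_lo(self) -> int:
        return min(self.cut_offset, len(self.recognition) - self.cut_offset)

    @property
    def cut_hi(self) -> int:
        return max(self.cut_offset, len(self.recognition) - self.cut_offset)

    @property
    def residual(self) -> str:
        """IUPAC pattern a read beginning at a junction of this enzyme starts with."""
        return self.recognition[self.cut_lo:]


#: SphI-HF: GCATG^C, 3' CATG overhang.
SPHI = EnzymeSpec("SphI", "GCATGC", 5)
#: BstYI: R^GATCY, 5' GATC overhang.
BSTYI = EnzymeSpec("BstYI", "RGATCY", 1)


@dataclass(frozen=True)
class SizeSelectSpec:
    """Gel size-selection window, adapter-inclusive.

    A fragment is retained iff ``min_len <= fragment_bp + adapter_extra
    <= max_len``.  Defaults mirror the 340-490 bp excision window with
    roughly 80 bp contributed by adapter ligation.
    """

    min_len: int = 340
    max_len: int = 490
    adapter_extra: int = 80

    def __post_init__(self) -> None:
        if self.min_len >= self.max_len:
            raise ValueError("min_len must be < max_len")
        if self.adapter_extra < 0:
            raise ValueError("adapter_extra must be >= 0")

    def keeps(self, fragment_bp: int) -> bool:
        return self.min_len <= fragment_bp + self.adapter_extra <= self.max_len


# ---------------------------------------------------------------------------
# reference simulation
# ---------------------------------------------------------------------------

#: The two worked loci of the assay panel reuse these contig ids.
DEFAULT_CONTIG_IDS = ("140238", "216845")


def _default_contig_ids(n: int) -> list[str]:
    ids = list(DEFAULT_CONTIG_IDS[:n])
    ids += [str(300001 + i) for i in range(n - len(ids))]
    return ids


def simulate_reference(
    n_contigs: int,
    contig_length: int,
    gc_fraction: float = 0.5,
    seed: int = 0,
    contig_ids: list[str] | None = None,
) -> dict[str, str]:
    """Random ancestral contigs, deterministic for a fixed seed."""
    if n_contigs < 1:
        raise ValueError("n_contigs must be >= 1")
    if contig_length < 200:
        raise ValueError("contig_length must be >= 200")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must be in [0, 1]")
    ids = list(contig_ids) if contig_ids is not None else _default_contig_ids(n_contigs)
    if len(ids) != n_contigs:
        raise ValueError("contig_ids length must equal n_contigs")
    rng = np.random.default_rng(seed)
    return {cid: random_dna(rng, contig_length, gc_fraction) for cid in ids}


def _scrub_sites(
    seq: str,
    keep: set[int],
    enzymes: tuple[EnzymeSpec, ...],
    rng: np.random.Generator,
) -> str:
    """Mutate away recognition-site matches except those starting in ``keep``."""
    s = list(seq)
    for _ in range(50):
        dirty = False
        for enz in enzymes:
            for m in find_iupac(enz.recognition, "".join(s)):
                if m in keep:
                    continue
                dirty = True
                j = m + len(enz.recognition) // 2
                allowed = [b for b in BASES
                           if b not in _iupac_set(enz.recognition[j - m])]
                s[j] = allowed[rng.integers(len(allowed))]
        if not dirty:
            return "".join(s)
    raise RuntimeError("could not scrub restriction sites")


def _iupac_set(code: str) -> str:
    from ._sequtil import IUPAC

    return IUPAC[code]


@dataclass(frozen=True)
class LocusInfo:
    """Where the engineered selectable fragment sits on a contig."""

    contig: str
    frag_start: int  # 0-based, duplex-inclusive
    frag_end: int
    #: positions inside the fragment guaranteed to be covered by read 1
    #: (SphI side) after 110 bp clipping, with margin from the residual site.
    variant_window: tuple[int, int]


def make_ddrad_reference(
    n_contigs: int,
    contig_length: int = 600,
    fragment_bp: int = 360,
    gc_fraction: float = 0.45,
    seed: int = 0,
    contig_ids: list[str] | None = None,
    enzymes: tuple[EnzymeSpec, EnzymeSpec] = (SPHI, BSTYI),
) -> tuple[dict[str, str], list[LocusInfo]]:
    """Reference contigs each carrying exactly one selectable ddRAD fragment.

    One SphI..BstYI cassette is written per contig such that the duplex
    fragment between the two junctions is ``fragment_bp`` long (within the
    340-490 bp adapter-inclusive window at the default); all other
    recognition-site matches are scrubbed so digestion of one contig yields
    exactly one selectable fragment at a known location.
    """
    enz_a, enz_b = enzymes
    if fragment_bp < 150 or fragment_bp + 40 > contig_length:
        raise ValueError("fragment_bp incompatible with contig_length")
    contigs = simulate_reference(n_contigs, contig_length, gc_fraction, seed, contig_ids)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xDD]))
    loci: list[LocusInfo] = []
    out: dict[str, str] = {}
    la, lb = len(enz_a.recognition), len(enz_b.recognition)
    for cid, seq in contigs.items():
        margin = (contig_length - (fragment_bp + enz_a.cut_lo + (lb - enz_b.cut_hi))) // 2
        m_a = max(margin, 1)
        # duplex fragment: [m_a + cut_lo, m_b + cut_hi); solve for m_b
        frag_start = m_a + enz_a.cut_lo
        frag_end = frag_start + fragment_bp
        m_b = frag_end - enz_b.cut_hi
        site_b = "".join(rng.choice(list(_iupac_set(c))) for c in enz_b.recognition)
        s = list(seq)
        s[m_a:m_a + la] = enz_a.recognition  # SphI site is concrete ACGT
        s[m_b:m_b + lb] = site_b
        scrubbed = _scrub_sites("".join(s), {m_a, m_b}, (enz_a, enz_b), rng)
        out[cid] = scrubbed
        # read 1 covers frag_start..frag_start+109 after clipping; keep clear
        # of the residual site and leave headroom for primer placement.
        win = (frag_start + 25, frag_start + 100)
        loci.append(LocusInfo(cid, frag_start, frag_end, win))
    return out, loci


# ---------------------------------------------------------------------------
# species models and variant planting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantSpec:
    """One planted substitution in one species.

    ``fixedness`` is the probability that an individual of the species
    carries ``allele`` (carriers carry it on both copies); non-carriers show
    ``noncarrier_allele`` (default: whatever the species background is).
    Fixed diagnostic sites use fixedness 1.0; the partially-segregating
    A. stellatus-like case uses fixedness < 1.
    """

    contig: str
    start: int  # 0-based
    allele: str
    species: str
    fixedness: float = 1.0
    noncarrier_allele: str | None = None

    def __post_init__(self) -> None:
        if not self.allele or any(b not in BASES for b in self.allele):
            raise ValueError(f"allele {self.allele!r} must be plain ACGT")
        if not 0.0 <= self.fixedness <= 1.0:
            raise ValueError("fixedness must be in [0, 1]")
        if self.noncarrier_allele is not None and (
            len(self.noncarrier_allele) != len(self.allele)
            or any(b not in BASES for b in self.noncarrier_allele)
        ):
            raise ValueError("noncarrier_allele must be ACGT of the same span")

    @property
    def end(self) -> int:
        return self.start + len(self.allele)


@dataclass
class SpeciesModel:
    """A species' fixed consensus haplotype plus its segregating sites."""

    name: str
    haplotypes: dict[str, str]
    planted: list[VariantSpec] = field(default_factory=list)

    def segregating(self) -> list[VariantSpec]:
        return [v for v in self.planted if v.fixedness < 1.0]


def diagnostic_specs(
    contig: str,
    start: int,
    target_species: str,
    target_allele: str,
    other_species: list[str],
    other_allele: str,
) -> list[VariantSpec]:
    """Convenience: one fixed diagnostic site expressed as per-species records."""
    specs = [VariantSpec(contig, start, target_allele, target_species)]
    specs += [VariantSpec(contig, start, other_allele, sp) for sp in other_species]
    return specs


def plant_variants(
    reference: dict[str, str],
    species: list[str],
    variants: list[VariantSpec],
    enzymes: tuple[EnzymeSpec, ...] = (SPHI, BSTYI),
) -> dict[str, SpeciesModel]:
    """Build per-species haplotypes from the reference plus planted variants.

    Fixed variants (fixedness 1) are written into the species haplotype;
    partially-segregating variants write their non-carrier background into
    the haplotype and are realized per individual by :func:`make_individual`.
    Variant spans must lie inside their contig, must not overlap each other
    within one species, and must not overlap (or create) a recognition-site
    match of the digestion enzymes, so that fragment boundaries are shared
    across species.
    """
    # pre-compute recognition matches on the reference
    site_spans: dict[str, list[tuple[int, int]]] = {}
    for cid, seq in reference.items():
        spans = []
        for enz in enzymes:
            spans += [(m, m + len(enz.recognition))
                      for m in find_iupac(enz.recognition, seq)]
        site_spans[cid] = spans

    by_species: dict[str, list[VariantSpec]] = {sp: [] for sp in species}
    for v in variants:
        if v.species not in by_species:
            raise ValueError(f"unknown species {v.species!r}")
        if v.contig not in reference:
            raise ValueError(f"unknown contig {v.contig!r}")
        if v.start < 0 or v.end > len(reference[v.contig]):
            raise ValueError(f"variant at {v.contig}:{v.start} outside contig")
        for lo, hi in site_spans[v.contig]:
            if v.start < hi and v.end > lo:
                raise ValueError(
                    f"variant at {v.contig}:{v.start} overlaps a "
                    f"restriction recognition site at {lo}-{hi}"
                )
        for w in by_species[v.species]:
            if w.contig == v.contig and v.start < w.end and v.end > w.start:
                raise ValueError(
                    f"overlapping variant spans at {v.contig}:{v.start} "
                    f"for species {v.species}"
                )
        by_species[v.species].append(v)

    models: dict[str, SpeciesModel] = {}
    for sp in species:
        haps = {cid: list(seq) for cid, seq in reference.items()}
        for v in by_species[sp]:
            written = v.allele if v.fixedness >= 1.0 else (
                v.noncarrier_allele or reference[v.contig][v.start:v.end]
            )
            haps[v.contig][v.start:v.end] = written
        hap_str = {cid: "".join(s) for cid, s in haps.items()}
        for cid, seq in hap_str.items():
            for enz in enzymes:
                if set(find_iupac(enz.recognition, seq)) != {
                    m for m, _ in site_spans[cid]
                    if iupac_any(enz, reference[cid], m)
                }:
                    raise ValueError(
                        f"planted alleles alter {enz.name} sites on contig {cid}"
                    )
        models[sp] = SpeciesModel(sp, hap_str, by_species[sp])
    return models


def iupac_any(enz: EnzymeSpec, seq: str, pos: int) -> bool:
    from ._sequtil import iupac_match

    return iupac_match(enz.recognition, seq, pos)


# ---------------------------------------------------------------------------
# individuals
# ---------------------------------------------------------------------------


@dataclass
class IndividualGenome:
    """A diploid individual: two haplotype copies per contig.

    Pure individuals draw both copies from one species model; F1 hybrids
    carry exactly one copy from each parent (copy 0 = first/maternal parent).
    """

    sample_id: str
    species_or_cross: str | tuple[str, str]
    copies: dict[str, tuple[str, str]]

    @property
    def is_hybrid(self) -> bool:
        return isinstance(self.species_or_cross, tuple)


def _sample_haplotype(model: SpeciesModel, rng: np.random.Generator) -> dict[str, str]:
    hap = {cid: seq for cid, seq in model.haplotypes.items()}
    for v in model.segregating():
        if rng.random() < v.fixedness:
            s = list(hap[v.contig])
            s[v.start:v.end] = v.allele
            hap[v.contig] = "".join(s)
    return hap


def make_individual(
    species_or_cross: str | tuple[str, str],
    models: dict[str, SpeciesModel],
    seed: int = 0,
    sample_id: str | None = None,
) -> IndividualGenome:
    """Construct a pure diploid or F1 hybrid individual.

    Partially-segregating sites are decided once per drawn parental
    haplotype set (a pure carrier is homozygous for the allele), which makes
    carrier status a per-individual Bernoulli(fixedness) draw as in the
    validation-panel counts this module emulates.
    """
    rng = np.random.default_rng(seed)
    if isinstance(species_or_cross, str):
        if species_or_cross not in models:
            raise ValueError(f"unknown species {species_or_cross!r}")
        hap = _sample_haplotype(models[species_or_cross], rng)
        copies = {cid: (seq, seq) for cid, seq in hap.items()}
        name = species_or_cross
    else:
        mother, father = species_or_cross
        for p in (mother, father):
            if p not in models:
                raise ValueError(f"unknown species {p!r}")
        hap_m = _sample_haplotype(models[mother], rng)
        hap_f = _sample_haplotype(models[father], rng)
        copies = {cid: (hap_m[cid], hap_f[cid]) for cid in hap_m}
        name = f"{mother}x{father}"
    sid = sample_id if sample_id is not None else name
    return IndividualGenome(sid, species_or_cross, copies)


# ---------------------------------------------------------------------------
# digestion and size selection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Fragment:
    """A size-selected double-digest fragment, oriented SphI -> BstYI.

    ``start``/``end`` are 0-based half-open duplex-inclusive coordinates on
    the source contig; ``seq`` is the top strand read 5'->3' from the
    enzyme-A (SphI) junction, i.e. reverse-complemented when the SphI site
    is the right-hand end on the contig's plus strand.
    """

    frag_id: str
    contig: str
    copy: int
    start: int
    end: int
    seq: str
    strand: str  # '+' if enzyme A is the left junction on the contig

    @property
    def length(self) -> int:
        return self.end - self.start


def _digest_sequence(
    seq: str,
    enz_a: EnzymeSpec,
    enz_b: EnzymeSpec,
    size_spec: SizeSelectSpec,
    contig: str,
    copy: int,
) -> list[Fragment]:
    events: list[tuple[int, int, EnzymeSpec]] = []
    for enz in (enz_a, enz_b):
        pats = {enz.recognition, revcomp(enz.recognition)}
        starts: set[int] = set()
        for p in pats:
            starts.update(find_iupac(p, seq))
        for m in sorted(starts):
            events.append((m + enz.cut_lo, m + enz.cut_hi, enz))
    events.sort(key=lambda e: e[0])
    frags: list[Fragment] = []
    for (lo1, hi1, e1), (lo2, hi2, e2) in itertools.pairwise(events):
        if e1.name == e2.name:
            continue
        start, end = lo1, hi2
        if end <= start:
            continue
        if not size_spec.keeps(end - start):
            continue
        sub = seq[start:end]
        if e1 is enz_a:
            oriented, strand = sub, "+"
        else:
            oriented, strand = revcomp(sub), "-"
        frags.append(Fragment(
            f"{contig}:{start}-{end}/{copy}", contig, copy, start, end,
            oriented, strand,
        ))
    return frags


def digest_and_select(
    genome: IndividualGenome | dict[str, str],
    enzyme_a: EnzymeSpec = SPHI,
    enzyme_b: EnzymeSpec = BSTYI,
    size_spec: SizeSelectSpec = SizeSelectSpec(),
) -> list[Fragment]:
    """In-silico double digestion plus size selection.

    Only fragments with one enzyme-A junction and one enzyme-B junction are
    kept (standard ddRAD chemistry: only mixed-end fragments receive both
    adapters), and only those whose adapter-inclusive length falls in the
    selection window.  Accepts a diploid individual (both copies digested)
    or a plain contig dict (single copy, e.g. the reference itself).
    """
    if enzyme_a.name == enzyme_b.name:
        raise ValueError("two distinct enzymes required")
    frags: list[Fragment] = []
    if isinstance(genome, IndividualGenome):
        for cid, (h0, h1) in sorted(genome.copies.items()):
            frags += _digest_sequence(h0, enzyme_a, enzyme_b, size_spec, cid, 0)
            frags += _digest_sequence(h1, enzyme_a, enzyme_b, size_spec, cid, 1)
    else:
        for cid, seq in sorted(genome.items()):
            frags += _digest_sequence(seq, enzyme_a, enzyme_b, size_spec, cid, 0)
    return frags


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReadPairRecord:
    """One barcoded paired-end read: read 1 from the SphI side (barcode +
    fragment prefix), read 2 from the BstYI side (reverse-complemented)."""

    read_id: str
    sample_id: str
    read1: str
    qual1: str
    read2: str
    qual2: str
    fragment_id: str


DEFAULT_READ_LEN = 125
_QCHAR = "?"  # constant Q30


def make_barcodes(samples: list[str], length: int = 6, seed: int = 0,
                  min_distance: int = 3) -> dict[str, str]:
    """Deterministic per-sample barcodes with pairwise Hamming distance >= 3."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xBC]))
    chosen: list[str] = []
    while len(chosen) < len(samples):
        cand = "".join(rng.choice(list(BASES), size=length))
        if all(hamming(cand, b) >= min_distance for b in chosen):
            chosen.append(cand)
    return dict(zip(samples, chosen))


def _check_barcodes(barcode_map: dict[str, str], min_distance: int = 3) -> None:
    codes = list(barcode_map.values())
    if len(set(len(c) for c in codes)) > 1:
        raise ValueError("barcodes must be equal length")
    for a, b in itertools.combinations(codes, 2):
        if hamming(a, b) < min_distance:
            raise ValueError(
                f"barcodes {a} and {b} closer than Hamming distance {min_distance}"
            )


def _mutate(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate <= 0.0:
        return seq
    arr = list(seq)
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    for i in hits:
        alts = [b for b in BASES if b != arr[i]]
        arr[i] = alts[rng.integers(3)]
    return "".join(arr)


def sequence_reads(
    fragments_by_sample: dict[str, list[Fragment]],
    barcode_map: dict[str, str],
    read_len: int = DEFAULT_READ_LEN,
    coverage: int = 20,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[ReadPairRecord]:
    """Emit ``coverage`` read pairs per fragment (per haplotype copy).

    Read 1 carries the sample barcode followed by the fragment prefix from
    the SphI junction; read 2 is the reverse complement of the fragment's
    BstYI end.  Substitution errors are i.i.d. per base at ``error_rate``
    over the full read, barcode included; qualities are constant Q30.
    """
    if coverage < 1:
        raise ValueError("coverage must be >= 1")
    _check_barcodes(barcode_map)
    rng = np.random.default_rng(seed)
    qual = _QCHAR * read_len
    out: list[ReadPairRecord] = []
    serial = 0
    for sample in sorted(fragments_by_sample):
        if sample not in barcode_map:
            raise ValueError(f"no barcode for sample {sample!r}")
        bc = barcode_map[sample]
        ins = read_len - len(bc)
        for frag in fragments_by_sample[sample]:
            if frag.length < max(ins, read_len):
                raise ValueError(
                    f"fragment {frag.frag_id} shorter than the read length"
                )
            r1_t = bc + frag.seq[:ins]
            r2_t = revcomp(frag.seq)[:read_len]
            for _ in range(coverage):
                out.append(ReadPairRecord(
                    f"sim:{serial}", sample,
                    _mutate(r1_t, rng, error_rate), qual,
                    _mutate(r2_t, rng, error_rate), qual,
                    frag.frag_id,
                ))
                serial += 1
    return out
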