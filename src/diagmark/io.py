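"""File formats, fixtures, configuration and the pipeline driver.

Conventions: FASTA/FASTQ through Biopython (gzip autodetected by filename);
tables are tab-separated UTF-8 with '#'-prefixed header lines, the last of
which names the columns; coordinates are 0-based half-open internally and
1-based inclusive in every user-facing table (stated in each header).  All
randomness flows from one configured seed, and every output table carries
the producing tool version and a config hash.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import logging
import sys
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from ._sequtil import BASES, random_dna
from .diagvar import DiagnosticConfig, DiagnosticVariant, call_diagnostics, screen_in_hybrid
from .ispcr import (
    BandPattern,
    BindingRule,
    PanelAssay,
    PanelConfig,
    classify,
    run_panel,
)
from .primerdesign import DesignConstraints, design_trio
from .readproc import ReadProcConfig, preprocess
from .refmap import (
    AlignmentRecord,
    MappingConfig,
    Pileup,
    build_pileup,
    map_reads,
    update_reference,
    write_sam,
)
from .simdata import (
    IndividualGenome,
    ReadPairRecord,
    SizeSelectSpec,
    VariantSpec,
    digest_and_select,
    make_barcodes,
    make_ddrad_reference,
    make_individual,
    plant_variants,
    sequence_reads,
)

log = logging.getLogger("diagmark")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[%(name)s] %(levelname)s %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)


# ---------------------------------------------------------------------------
# basic sequence file I/O
# ---------------------------------------------------------------------------


def _open_text(path: str | Path, mode: str = "rt") -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> dict[str, str]:
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper()
                for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(path: str | Path, records: dict[str, str]) -> None:
    with _open_text(path, "wt") as fh:
        SeqIO.write(
            (SeqRecord(Seq(seq), id=name, description="")
             for name, seq in records.items()),
            fh, "fasta")


def write_fastq_pairs(
    pairs: Iterable[ReadPairRecord], path1: str | Path, path2: str | Path
) -> None:
    with _open_text(path1, "wt") as f1, _open_text(path2, "wt") as f2:
        for p in pairs:
            f1.write(f"@{p.read_id}/1\n{p.read1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.read_id}/2\n{p.read2}\n+\n{p.qual2}\n")


def read_fastq_pairs(path1: str | Path, path2: str | Path) -> list[ReadPairRecord]:
    """Read mate files into pair records, checking id agreement per record."""
    pairs: list[ReadPairRecord] = []
    with _open_text(path1) as f1, _open_text(path2) as f2:
        it1 = SeqIO.parse(f1, "fastq")
        it2 = SeqIO.parse(f2, "fastq")
        for n, (r1, r2) in enumerate(zip(it1, it2, strict=True), start=1):
            id1, id2 = r1.id.removesuffix("/1"), r2.id.removesuffix("/2")
            if id1 != id2:
                raise ValueError(
                    f"mismatched read ids at record {n}: {r1.id!r} vs {r2.id!r}")
            pairs.append(ReadPairRecord(
                id1, "", str(r1.seq).upper(),
                "".join(chr(q + 33) for q in r1.letter_annotations["phred_quality"]),
                str(r2.seq).upper(),
                "".join(chr(q + 33) for q in r2.letter_annotations["phred_quality"]),
                "",
            ))
    return pairs


# ---------------------------------------------------------------------------
# '#'-headed TSV tables
# ---------------------------------------------------------------------------


def write_table(
    path: str | Path,
    columns: Sequence[str],
    rows: Iterable[Sequence],
    meta: Sequence[str] = (),
) -> None:
    with _open_text(path, "wt") as fh:
        for line in meta:
            fh.write(f"# {line}\n")
        fh.write("#" + "\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def read_table(path: str | Path) -> list[dict[str, str]]:
    columns: list[str] | None = None
    rows: list[dict[str, str]] = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body and "\t" in line:
                    columns = line.lstrip("#").split("\t")
                elif body and columns is None:
                    columns = None
                continue
            if columns is None:
                raise ValueError(f"{path}: data before '#'-prefixed header")
            vals = line.split("\t")
            rows.append(dict(zip(columns, vals)))
    return rows


def table_meta(seed: int | None, config_hash: str, extra: Sequence[str] = ()) -> list[str]:
    meta = [f"diagmark {__version__} config={config_hash}"
            + (f" seed={seed}" if seed is not None else ""),
            "coordinates are 1-based inclusive"]
    return meta + list(extra)


def config_hash(config: dict) -> str:
    return hashlib.md5(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------


def write_manifest(
    path: str | Path,
    rows: list[tuple[str, str, str]],  # sample_id, barcode, species_or_cross
    meta: Sequence[str] = (),
) -> None:
    seen = set()
    for sid, bc, _ in rows:
        if sid in seen:
            raise ValueError(f"duplicate sample id {sid!r}")
        seen.add(sid)
    write_table(path, ("sample_id", "barcode", "species_or_cross"), rows, meta)


def read_manifest(path: str | Path) -> list[tuple[str, str, str | tuple[str, str]]]:
    out = []
    for row in read_table(path):
        soc: str | tuple[str, str] = row["species_or_cross"]
        if " x " in soc:
            mother, father = soc.split(" x ", 1)
            soc = (mother, father)
        out.append((row["sample_id"], row["barcode"], soc))
    return out


def species_label(species_or_cross: str | tuple[str, str]) -> str:
    if isinstance(species_or_cross, tuple):
        return f"{species_or_cross[0]}x{species_or_cross[1]}"
    return species_or_cross


# ---------------------------------------------------------------------------
# assay panel fixture
# ---------------------------------------------------------------------------


def _data_path(name: str) -> Path:
    return Path(str(resources.files("diagmark").joinpath("data", name)))


def load_panel(path: str | Path | None = None) -> PanelConfig:
    """Load an assay panel table (default: the published two-locus fixture).

    Columns: assay, role (positive|negative|common), primer, sequence,
    product_bp, target_species.  Sequences are normalized to uppercase;
    every assay must have exactly one primer per role.
    """
    path = _data_path("table1_panel.tsv") if path is None else path
    rows = read_table(path)
    by_assay: dict[str, dict[str, tuple[str, str]]] = {}
    meta: dict[str, tuple[str, int]] = {}
    order: list[str] = []
    for row in rows:
        assay = row["assay"]
        role = row["role"]
        seq = row["sequence"].upper()
        if any(b not in BASES for b in seq):
            raise ValueError(
                f"panel assay {assay}: non-ACGT character in {row['primer']}")
        if assay not in by_assay:
            by_assay[assay] = {}
            order.append(assay)
        if role in by_assay[assay]:
            raise ValueError(f"panel assay {assay}: duplicate role {role}")
        by_assay[assay][role] = (row["primer"], seq)
        meta[assay] = (row["target_species"], int(row["product_bp"]))
    assays = []
    for assay in order:
        roles = by_assay[assay]
        missing = {"positive", "negative", "common"} - set(roles)
        if missing:
            raise ValueError(f"panel assay {assay}: missing {sorted(missing)}")
        target, product = meta[assay]
        assays.append(PanelAssay(
            assay, target,
            roles["positive"][0], roles["positive"][1],
            roles["negative"][0], roles["negative"][1],
            roles["common"][0], roles["common"][1],
            product,
        ))
    # the published cycling program, carried verbatim for reports
    protocol = (
        ("annealing_c", "63"),
        ("cycling", "95C 120s; 5x(95C 60s, 63C 60s, 72C 60s); "
                    "25x(95C 30s, 63C 30s, 72C 60s); 72C 720s"),
    )
    return PanelConfig(tuple(assays), protocol)


def load_validation_counts(
    path: str | Path | None = None,
) -> dict[tuple[str, str], tuple[int, int]]:
    """Published per-pair validation counts: (pair, species) -> (amplified, total)."""
    path = _data_path("table1_validation.tsv") if path is None else path
    return {
        (row["pair"], row["species"]): (int(row["amplified"]), int(row["total"]))
        for row in read_table(path)
    }


# ---------------------------------------------------------------------------
# synthetic locus templates for the fixture panel
# ---------------------------------------------------------------------------

_TEMPLATE_FLANK = 30


def synthetic_locus_template(assay: PanelAssay, allele: str, flank: int = _TEMPLATE_FLANK) -> str:
    """A synthetic template carrying ``allele`` at the assay's diagnostic 3'
    position(s).

    The published loci are known only through their primers and product
    sizes, so the template reconstructs the primer-binding geometry —
    forward site (with the true penultimate base restored where the primer
    carries the deliberate mismatch), deterministic filler, reverse-
    complemented common-primer site — and invents flanks.  Purely synthetic
    sequence; product sizes match the assay's declared length.
    """
    p, n = assay.positive, assay.negative
    if len(p) != len(n):
        raise ValueError("positive/negative primers must be equal length")
    diff = [i for i in range(len(p)) if p[i] != n[i]]
    if diff and diff[-1] != len(p) - 1:
        raise ValueError("allele-specific difference must be 3'-terminal")
    span = 2 if len(diff) == 2 and diff[0] == len(p) - 2 else 1
    if len(allele) != span:
        raise ValueError(
            f"assay {assay.name} expects a {span}-base allele, got {allele!r}")
    fwd_site = list(p)
    if span == 1:
        # restore a plausible true penultimate base: the primer's is the
        # deliberate mismatch, so pick a base it does not match
        fwd_site[-2] = "A" if p[-2] != "A" else "C"
    fwd_site[-span:] = allele
    filler_len = assay.product_bp - len(p) - len(assay.common)
    if filler_len < 0:
        raise ValueError("product shorter than the two primers")
    rng = np.random.default_rng(
        int.from_bytes(hashlib.md5(assay.name.encode()).digest()[:4], "big"))
    from ._sequtil import revcomp

    flank5 = random_dna(rng, flank)
    filler = random_dna(rng, filler_len)
    flank3 = random_dna(rng, flank)
    return flank5 + "".join(fwd_site) + filler + revcomp(assay.common) + flank3


def genotype_templates(
    panel: PanelConfig,
    genotypes: dict[str, dict[str, tuple[str, str]]],
) -> dict[str, list[str]]:
    """Expand per-locus allele pairs into synthetic haplotype templates.

    ``genotypes``: sample -> {assay name -> (allele_a, allele_b)}.
    """
    assays = {a.name: a for a in panel.assays}
    out: dict[str, list[str]] = {}
    for sample, loci in genotypes.items():
        templates: list[str] = []
        for assay_name, (a, b) in loci.items():
            assay = assays[assay_name]
            templates.append(synthetic_locus_template(assay, a))
            templates.append(synthetic_locus_template(assay, b))
        out[sample] = templates
    return out


def read_genotypes(path: str | Path) -> dict[str, dict[str, tuple[str, str]]]:
    """Genotype table: columns sample_id, assay, allele_a, allele_b."""
    out: dict[str, dict[str, tuple[str, str]]] = {}
    for row in read_table(path):
        out.setdefault(row["sample_id"], {})[row["assay"]] = (
            row["allele_a"].upper(), row["allele_b"].upper())
    return out


# ---------------------------------------------------------------------------
# alignment serialization
# ---------------------------------------------------------------------------


def format_cigar(ops: tuple[tuple[str, int], ...]) -> str:
    return "".join(f"{n}{op}" for op, n in ops)


def parse_cigar(cigar: str) -> tuple[tuple[str, int], ...]:
    ops: list[tuple[str, int]] = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            ops.append((ch, int(num)))
            num = ""
    return tuple(ops)


_ALN_COLS = ("read_id", "sample", "species", "contig", "start_1based",
             "strand", "cigar", "score", "mismatches", "seq")


def write_alignments(
    path: str | Path,
    alignments: list[tuple[str, str, AlignmentRecord]],  # (sample, species, aln)
    meta: Sequence[str] = (),
) -> None:
    rows = [
        (a.read_id, sample, species, a.contig, a.start + 1, a.strand,
         format_cigar(a.ops), a.score, a.mismatches, a.seq)
        for sample, species, a in alignments
    ]
    write_table(path, _ALN_COLS, rows, meta)


def read_alignments(path: str | Path) -> list[tuple[str, str, AlignmentRecord]]:
    out = []
    for row in read_table(path):
        out.append((
            row["sample"], row["species"],
            AlignmentRecord(
                row["read_id"], row["contig"], int(row["start_1based"]) - 1,
                row["strand"], parse_cigar(row["cigar"]),
                int(row["score"]), int(row["mismatches"]), row["seq"],
            )))
    return out


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

STAGES = ("simulate", "preprocess", "map", "callvars", "design", "identify")


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def default_config() -> dict:
    with open(_data_path("demo_config.yaml")) as fh:
        return yaml.safe_load(fh)


class PipelineError(RuntimeError):
    pass


def _require(outdir: Path, name: str, producer: str) -> Path:
    p = outdir / name
    if not p.exists():
        raise PipelineError(
            f"missing input {name}: run the '{producer}' stage first")
    return p


def _seed_for(seed: int, stage: str) -> int:
    h = hashlib.md5(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def stage_simulate(cfg: dict, outdir: Path, seed: int, chash: str) -> dict:
    sc = cfg.get("simulate", {})
    sseed = _seed_for(seed, "simulate")
    species = list(sc.get("species", ["A_ruthenus", "H_huso", "A_baerii"]))
    reference, loci = make_ddrad_reference(
        n_contigs=int(sc.get("n_contigs", 4)),
        contig_length=int(sc.get("contig_length", 600)),
        fragment_bp=int(sc.get("fragment_bp", 360)),
        gc_fraction=float(sc.get("gc_fraction", 0.45)),
        seed=sseed,
    )
    locus_list = list(loci)
    variants: list[VariantSpec] = []
    for d in sc.get("diagnostics", []):
        locus = locus_list[int(d["locus"])]
        pos = locus.variant_window[0] + int(d.get("offset", 10))
        target = d["target"]
        t_allele = d["target_allele"].upper()
        o_allele = d["other_allele"].upper()
        fixed = float(d.get("fixedness", 1.0))
        noncarrier = d.get("noncarrier_allele")
        for sp in species:
            if sp == target:
                variants.append(VariantSpec(
                    locus.contig, pos, t_allele, sp, fixed,
                    noncarrier.upper() if noncarrier else None))
            else:
                variants.append(VariantSpec(locus.contig, pos, o_allele, sp))
    models = plant_variants(reference, species, variants)
    ref_species = sc.get("reference_species", species[0])
    # the mapping reference is the reference-species consensus, as in a
    # draft genome assembled from the target species
    map_reference = dict(models[ref_species].haplotypes)
    sample_rows = []
    genomes: dict[str, IndividualGenome] = {}
    for i, s in enumerate(sc.get("samples", [])):
        sid = s["sample_id"]
        soc = tuple(s["cross"]) if "cross" in s else s["species"]
        genomes[sid] = make_individual(
            soc, models, seed=_seed_for(sseed, f"ind:{sid}"), sample_id=sid)
        sample_rows.append((sid, soc))
    barcodes = make_barcodes([sid for sid, _ in sample_rows], seed=sseed)
    size_spec = SizeSelectSpec(
        int(sc.get("size_min", 340)), int(sc.get("size_max", 490)),
        int(sc.get("adapter_extra", 80)))
    frags_by_sample = {
        sid: digest_and_select(genomes[sid], size_spec=size_spec)
        for sid, _ in sample_rows
    }
    pairs = sequence_reads(
        frags_by_sample, barcodes,
        read_len=int(sc.get("read_len", 125)),
        coverage=int(sc.get("coverage", 20)),
        error_rate=float(sc.get("error_rate", 0.0)),
        seed=_seed_for(sseed, "reads"),
    )
    meta = table_meta(seed, chash)
    write_fasta(outdir / "reference.fasta", map_reference)
    gdir = outdir / "genomes"
    gdir.mkdir(exist_ok=True)
    for sid, g in genomes.items():
        recs = {}
        for cid, (h0, h1) in sorted(g.copies.items()):
            recs[f"{cid}|copy0"] = h0
            recs[f"{cid}|copy1"] = h1
        write_fasta(gdir / f"{sid}.fasta", recs)
    write_manifest(
        outdir / "manifest.tsv",
        [(sid, barcodes[sid],
          " x ".join(soc) if isinstance(soc, tuple) else soc)
         for sid, soc in sample_rows],
        meta)
    write_table(
        outdir / "loci.tsv",
        ("contig", "frag_start_1based", "frag_end_1based"),
        [(lo.contig, lo.frag_start + 1, lo.frag_end) for lo in locus_list],
        meta)
    write_fastq_pairs(pairs, outdir / "reads_1.fastq", outdir / "reads_2.fastq")
    n_frag = sum(len(v) for v in frags_by_sample.values())
    log.info("simulate: %d contigs, %d samples, %d fragments, %d read pairs "
             "(seed %d)", len(reference), len(sample_rows), n_frag, len(pairs),
             sseed)
    return {"contigs": len(reference), "samples": len(sample_rows),
            "fragments": n_frag, "read_pairs": len(pairs),
            "planted_variants": len(sc.get("diagnostics", []))}


def stage_preprocess(cfg: dict, outdir: Path, seed: int, chash: str) -> dict:
    pc = cfg.get("preprocess", {})
    config = ReadProcConfig(
        barcode_max_mismatch=int(pc.get("barcode_max_mismatch", 1)),
        clip_length=int(pc.get("clip_length", 110)),
    )
    manifest = read_manifest(_require(outdir, "manifest.tsv", "simulate"))
    barcode_map = {sid: bc for sid, bc, _ in manifest}
    pairs = read_fastq_pairs(
        _require(outdir, "reads_1.fastq", "simulate"),
        _require(outdir, "reads_2.fastq", "simulate"))
    by_sample, discards = preprocess(pairs, barcode_map, config)
    pdir = outdir / "processed"
    pdir.mkdir(exist_ok=True)
    for sid, sample_pairs in by_sample.items():
        write_fastq_pairs(sample_pairs, pdir / f"{sid}_1.fastq",
                          pdir / f"{sid}_2.fastq")
    meta = table_meta(seed, chash)
    write_table(outdir / "discard_log.tsv", ("read_id", "reason"),
                discards.records, meta)
    kept = sum(len(v) for v in by_sample.values())
    log.info("preprocess: %d pairs in, %d kept, %d discarded %s",
             len(pairs), kept, len(discards), dict(discards.counts()))
    return {"pairs_in": len(pairs), "pairs_kept": kept,
            "discarded": dict(discards.counts())}


def stage_map(cfg: dict, outdir: Path, seed: int, chash: str) -> dict:
    mc = cfg.get("map", {})
    config = MappingConfig(
        mismatch_cost=int(mc.get("mismatch_cost", 2)),
        max_gap_length=int(mc.get("max_gap_length", 3)),
        max_gaps=int(mc.get("max_gaps", 1)),
        min_fraction_aligned=float(mc.get("min_fraction_aligned", 0.9)),
    )
    reference = read_fasta(_require(outdir, "reference.fasta", "simulate"))
    manifest = read_manifest(_require(outdir, "manifest.tsv", "simulate"))
    ref_species = cfg.get("simulate", {}).get(
        "reference_species", species_label(manifest[0][2]))
    pdir = outdir / "processed"
    reads_by_sample: dict[str, list[tuple[str, str]]] = {}
    for sid, _, _ in manifest:
        p1 = _require(outdir, f"processed/{sid}_1.fastq", "preprocess")
        p2 = pdir / f"{sid}_2.fastq"
        single: list[tuple[str, str]] = []
        for pair in read_fastq_pairs(p1, p2):
            single.append((f"{pair.read_id}/1", pair.read1))
            single.append((f"{pair.read_id}/2", pair.read2))
        reads_by_sample[sid] = single
    # pass 1: reference-species reads drive the majority-base update
    ref_samples = [sid for sid, _, soc in manifest
                   if species_label(soc) == ref_species]
    pass1_reads = [r for sid in ref_samples for r in reads_by_sample[sid]]
    aln1, _ = map_reads(pass1_reads, reference, config)
    updated, removed = update_reference(reference, aln1)
    # pass 2: all samples against the updated contigs
    all_alignments: list[tuple[str, str, AlignmentRecord]] = []
    unmapped_count = 0
    for sid, _, soc in manifest:
        alns, unmapped = map_reads(reads_by_sample[sid], updated, config)
        unmapped_count += len(unmapped)
        sp = species_label(soc)
        all_alignments += [(sid, sp, a) for a in alns]
    meta = table_meta(seed, chash)
    write_fasta(outdir / "updated_reference.fasta", updated)
    (outdir / "removed_contigs.txt").write_text(
        "".join(f"{cid}\n" for cid in removed))
    write_alignments(outdir / "alignments.tsv", all_alignments, meta)
    write_sam(str(outdir / "alignments.sam"),
              [a for _, _, a in all_alignments], updated)
    log.info("map: %d reads mapped, %d unmapped, %d contigs removed",
             len(all_alignments), unmapped_count, len(removed))
    return {"mapped": len(all_alignments), "unmapped": unmapped_count,
            "removed_contigs": removed}


def _pileup_from_outdir(outdir: Path) -> tuple[Pileup, dict[str, str]]:
    updated = read_fasta(_require(outdir, "updated_reference.fasta", "map"))
    triples = read_alignments(_require(outdir, "alignments.tsv", "map"))
    by_species: dict[str, list[AlignmentRecord]] = {}
    for _, species, aln in triples:
        by_species.setdefault(species, []).append(aln)
    return build_pileup(by_species, updated), updated


def stage_callvars(cfg: dict, outdir: Path, seed: int, chash: str) -> dict:
    vc = cfg.get("callvars", {})
    pileup, _ = _pileup_from_outdir(outdir)
    manifest = read_manifest(_require(outdir, "manifest.tsv", "simulate"))
    meta = table_meta(seed, chash)
    rows = []
    all_variants: list[DiagnosticVariant] = []
    for tdef in vc.get("targets", []):
        config = DiagnosticConfig(
            target_species=tdef["target"],
            contrast_species=tuple(tdef["contrasts"]),
            min_coverage=int(vc.get("min_coverage", 32)),
            fixedness_tolerance=float(vc.get("fixedness_tolerance", 0.0)),
        )
        variants = call_diagnostics(pileup, config)
        all_variants += variants
        for v in variants:
            rows.append((
                v.contig, v.start + 1, v.end, v.span, v.target_allele,
                v.non_target_allele, v.target_species, v.rule,
                ";".join(f"{sp}:{d}" for sp, d in v.depths),
            ))
    write_table(
        outdir / "variants.tsv",
        ("contig", "start_1based", "end_1based", "span", "target_allele",
         "non_target_allele", "target_species", "rule", "depths"),
        rows, meta)
    # screen putative diagnostics in any F1 hybrid sample of the two targets
    screen_rows = []
    hybrids = [(sid, soc) for sid, _, soc in manifest if isinstance(soc, tuple)]
    for sid, soc in hybrids:
        label = species_label(soc)
        if label not in pileup.species:
            continue
        verdicts = screen_in_hybrid(all_variants, pileup, label,
                                    int(vc.get("min_each_allele", 1)))
        for v, verdict in verdicts.items():
            screen_rows.append((sid, v.contig, v.start + 1, v.target_allele,
                                v.non_target_allele, verdict))
    write_table(
        outdir / "hybrid_screen.tsv",
        ("sample_id", "contig", "start_1based", "target_allele",
         "non_target_allele", "verdict"),
        screen_rows, meta)
    log.info("callvars: %d diagnostic variants, %d hybrid-screen rows",
             len(all_variants), len(screen_rows))
    return {"variants": len(all_variants),
            "hybrid_screen": {r[5]: sum(1 for x in screen_rows if x[5] == r[5])
                              for r in screen_rows} if screen_rows else {}}


def stage_design(cfg: dict, outdir: Path, seed: int, chash: str) -> dict:
    dc = cfg.get("design", {})
    constraints = DesignConstraints(
        primer_len_min=int(dc.get("primer_len_min", 18)),
        primer_len_max=int(dc.get("primer_len_max", 25)),
        amplicon_min=int(dc.get("amplicon_min", 100)),
        amplicon_max=int(dc.get("amplicon_max", 300)),
        tm_target=float(dc.get("tm_target", 60.0)),
    )
    pileup, updated = _pileup_from_outdir(outdir)
    vrows = read_table(_require(outdir, "variants.tsv", "callvars"))
    meta = table_meta(seed, chash)
    panel_rows = []
    n_designed = 0
    for i, row in enumerate(vrows):
        v = DiagnosticVariant(
            row["contig"], int(row["start_1based"]) - 1,
            int(row["end_1based"]), row["target_allele"],
            row["non_target_allele"], row["target_species"], row["rule"],
        )
        name = f"dv{i + 1}_{v.target_species}"
        try:
            trios = design_trio(v.contig, updated[v.contig], v, pileup,
                                constraints, name=name)
        except Exception as exc:  # explicit failure with diagnosis
            log.warning("design: %s failed: %s", name, exc)
            continue
        best = trios[0]
        n_designed += 1
        for role, pname, seq in (
                ("positive", f"{name}_p", best.positive),
                ("negative", f"{name}_n", best.negative),
                ("common", f"{name}_uni", best.common)):
            panel_rows.append((name, role, pname, seq,
                               best.amplicon_positive, v.target_species))
    write_table(
        outdir / "panel_designed.tsv",
        ("assay", "role", "primer", "sequence", "product_bp", "target_species"),
        panel_rows, meta)
    log.info("design: %d/%d variants yielded a primer trio",
             n_designed, len(vrows))
    return {"variants_in": len(vrows), "trios_designed": n_designed}


def stage_identify(cfg: dict, outdir: Path, seed: int, chash: str) -> dict:
    ic = cfg.get("identify", {})
    panel_src = ic.get("panel", "designed")
    if panel_src == "fixture":
        panel = load_panel()
    elif panel_src == "designed":
        panel = load_panel(_require(outdir, "panel_designed.tsv", "design"))
    else:
        panel = load_panel(panel_src)
    rule = BindingRule(max_product=int(ic.get("max_product", 1500)))
    genotype_tsv = ic.get("genotypes")
    if genotype_tsv:
        samples = genotype_templates(panel, read_genotypes(genotype_tsv))
        patterns = run_panel(samples, panel, rule)
    else:
        gdir = _require(outdir, "genomes", "simulate")
        samples = {}
        for fa in sorted(Path(gdir).glob("*.fasta")):
            samples[fa.stem] = list(read_fasta(fa).values())
        patterns = run_panel(samples, panel, rule)
    calls = [classify(p, panel) for p in patterns]
    meta = table_meta(seed, chash)
    rows = []
    for p, c in zip(patterns, calls):
        band_str = ",".join(
            f"{b}{'+' if p.bands[b] else '-'}" for b in panel.band_ids())
        size_str = ",".join(
            str(p.sizes[b]) for b in panel.band_ids() if p.sizes[b])
        rows.append((p.sample_id, band_str, size_str or "-", c.verdict,
                     ";".join(c.caveats) or "-"))
    write_table(
        outdir / "identification.tsv",
        ("sample_id", "bands", "product_bp", "verdict", "caveats"),
        rows, meta)
    with open(outdir / "identification.json", "w") as fh:
        json.dump([{
            "sample_id": c.sample_id, "verdict": c.verdict,
            "species_1": c.species_1, "species_2": c.species_2,
            "bands": dict(p.bands), "caveats": list(c.caveats),
        } for p, c in zip(patterns, calls)], fh, indent=2)
    log.info("identify: %d samples classified", len(calls))
    return {"samples": len(calls),
            "verdicts": {c.verdict: sum(1 for x in calls
                                        if x.verdict == c.verdict)
                         for c in calls}}


_STAGE_FN = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "map": stage_map,
    "callvars": stage_callvars,
    "design": stage_design,
    "identify": stage_identify,
}


def pipeline_run(
    config: dict | str | Path,
    outdir: str | Path,
    seed: int = 1,
    stages: Sequence[str] | None = None,
) -> dict:
    """Run the pipeline stages in order, writing artifacts to ``outdir``.

    Any contiguous stage subset is runnable provided the preceding stages'
    outputs are present in ``outdir``.  Returns (and writes) a summary of
    per-stage counts.
    """
    cfg = load_config(config) if isinstance(config, (str, Path)) else config
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)
    wanted = list(stages) if stages else list(STAGES)
    for st in wanted:
        if st not in STAGES:
            raise ValueError(f"unknown stage {st!r}; stages are {STAGES}")
    wanted.sort(key=STAGES.index)
    log.info("pipeline: stages %s, seed %d, config %s", wanted, seed, chash)
    summary: dict = {"seed": seed, "config_hash": chash,
                     "version": __version__, "stages": {}}
    for st in wanted:
        summary["stages"][st] = _STAGE_FN[st](cfg, outdir, seed, chash)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    return summary
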