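"""Reference mapping, majority-base contig updating, and per-species pileups.

The mapper is a transparent seed-and-extend re-implementation of the
mapping stage of the discovery pipeline: exact k-mer seeds (default k=21)
propose candidate placements, which are scored under a simple affine-free
cost model mirroring the published parameters — mismatch cost 2, at most
one gap run of length <= 3 (flat penalty), acceptance when at least 90% of
the read aligns as matches.  A read is assigned to its unique best-scoring
placement; best-score ties are logged as ambiguous and excluded from
pileups.

Contig post-processing follows the same pipeline: contigs with no mapped
reads are removed, and every covered position is updated to the strict
majority base among covering reads (ties keep the original reference base,
a single correction round).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from ._sequtil import revcomp, seq_to_array

UNMAPPED_NO_SEED = "no_seed"
UNMAPPED_LOW_SCORE = "low_score"
UNMAPPED_AMBIGUOUS = "ambiguous"

_BASE_IDX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_IDX[_b] = _i
_IDX_BASE = "ACGT"


@dataclass(frozen=True)
class MappingConfig:
    mismatch_cost: int = 2
    max_gap_length: int = 3
    max_gaps: int = 1
    min_fraction_aligned: float = 0.9
    seed_k: int = 21
    gap_penalty: int = 3
    max_seed_hits: int = 32

    def __post_init__(self) -> None:
        if min(self.mismatch_cost, self.max_gap_length, self.max_gaps) < 0:
            raise ValueError("costs and gap limits must be non-negative")
        if not 0.0 < self.min_fraction_aligned <= 1.0:
            raise ValueError("min_fraction_aligned must be in (0, 1]")


@dataclass(frozen=True)
class AlignmentRecord:
    """One accepted placement; ``seq`` is reference-strand oriented."""

    read_id: str
    contig: str
    start: int
    strand: str
    ops: tuple[tuple[str, int], ...]  # M / D (ref skip) / I (read skip)
    score: int
    mismatches: int
    seq: str

    def ref_span(self) -> int:
        return sum(n for op, n in self.ops if op in "MD")

    def aligned_base(self, ref_pos: int) -> str | None:
        """Read base aligned at ``ref_pos``, None if not covered (or gapped)."""
        rpos, qpos = self.start, 0
        for op, n in self.ops:
            if op == "M":
                if rpos <= ref_pos < rpos + n:
                    return self.seq[qpos + (ref_pos - rpos)]
                rpos += n
                qpos += n
            elif op == "D":
                if rpos <= ref_pos < rpos + n:
                    return None
                rpos += n
            else:  # I
                qpos += n
        return None


# ---------------------------------------------------------------------------
# alignment scoring
# ---------------------------------------------------------------------------


def _score_at(
    read: np.ndarray,
    ref: np.ndarray,
    start: int,
    config: MappingConfig,
) -> tuple[int, int, tuple[tuple[str, int], ...]] | None:
    """Best alignment of ``read`` anchored with its first base at ``start``,
    allowing at most one gap run of length <= max_gap_length.

    Returns (score, mismatches, ops) or None if out of bounds.
    """
    L = len(read)
    n = len(ref)
    if start < 0 or start + L > n:
        return None
    window = ref[start:start + L]
    cmp0 = read != window
    pre = np.concatenate(([0], np.cumsum(cmp0)))
    mm0 = int(pre[-1])
    best = (L - mm0 - config.mismatch_cost * mm0, mm0, (("M", L),))
    if config.max_gaps >= 1:
        for g in range(1, config.max_gap_length + 1):
            # deletion: read[i:] aligns at start+i+g
            if start + L + g <= n:
                cmp_d = read != ref[start + g:start + g + L]
                suf = np.concatenate((np.cumsum(cmp_d[::-1])[::-1], [0]))
                i = int(np.argmin(pre[1:L] + suf[1:L])) + 1
                mm = int(pre[i] + suf[i])
                score = (L - mm) - config.mismatch_cost * mm - config.gap_penalty
                if score > best[0]:
                    best = (score, mm, (("M", i), ("D", g), ("M", L - i)))
            # insertion: read[i:i+g] unaligned; read[i+g:] aligns at start+i
            if L - g >= 1:
                cmp_i = read[g:] != window[:L - g]
                suf_i = np.concatenate((np.cumsum(cmp_i[::-1])[::-1], [0]))
                k = L - g  # split i ranges 1..k-1? allow 1..k
                i = int(np.argmin(pre[1:k] + suf_i[1:k])) + 1 if k > 1 else 1
                mm = int(pre[i] + suf_i[i])
                aligned = L - g
                score = (aligned - mm) - config.mismatch_cost * mm - config.gap_penalty
                if score > best[0]:
                    best = (score, mm,
                            (("M", i), ("I", g), ("M", L - g - i)))
    return best


def _seed_index(
    contigs: dict[str, str], k: int, max_hits: int
) -> dict[str, list[tuple[str, int]]]:
    index: dict[str, list[tuple[str, int]]] = defaultdict(list)
    for cid, seq in contigs.items():
        for i in range(0, len(seq) - k + 1):
            index[seq[i:i + k]].append((cid, i))
    return {kmer: hits for kmer, hits in index.items() if len(hits) <= max_hits}


def map_reads(
    reads: Iterable[tuple[str, str]],
    contigs: dict[str, str],
    config: MappingConfig = MappingConfig(),
) -> tuple[list[AlignmentRecord], list[tuple[str, str]]]:
    """Map single-end reads (id, sequence) to contigs.

    Each read is placed at its best-scoring candidate location over both
    strands; the placement must be unique at the best score and must align
    at least ``min_fraction_aligned`` of the read as matches.
    """
    if not contigs:
        raise ValueError("contigs must be non-empty")
    k = config.seed_k
    index = _seed_index(contigs, k, config.max_seed_hits)
    arrays = {cid: seq_to_array(seq) for cid, seq in contigs.items()}
    alignments: list[AlignmentRecord] = []
    unmapped: list[tuple[str, str]] = []
    deltas = range(-config.max_gap_length, config.max_gap_length + 1)
    for read_id, seq in reads:
        L = len(seq)
        if L < k:
            unmapped.append((read_id, UNMAPPED_NO_SEED))
            continue
        offsets = sorted({0, (L - k) // 2, L - k})
        candidates: set[tuple[str, int, str]] = set()
        oriented = {"+": seq, "-": revcomp(seq)}
        for strand, s in oriented.items():
            for off in offsets:
                for cid, pos in index.get(s[off:off + k], ()):
                    for d in deltas:
                        candidates.add((cid, pos - off + d, strand))
        if not candidates:
            unmapped.append((read_id, UNMAPPED_NO_SEED))
            continue
        read_arrs = {st: seq_to_array(s) for st, s in oriented.items()}
        scored: list[tuple[int, int, tuple, str, int, str]] = []
        for cid, start, strand in candidates:
            res = _score_at(read_arrs[strand], arrays[cid], start, config)
            if res is not None:
                scored.append((res[0], res[1], res[2], cid, start, strand))
        if not scored:
            unmapped.append((read_id, UNMAPPED_LOW_SCORE))
            continue
        best_score = max(s[0] for s in scored)
        top = [s for s in scored if s[0] == best_score]
        if len(top) > 1:
            unmapped.append((read_id, UNMAPPED_AMBIGUOUS))
            continue
        score, mm, ops, cid, start, strand = top[0]
        matches = L - mm - sum(n for op, n in ops if op == "I")
        if matches / L < config.min_fraction_aligned:
            unmapped.append((read_id, UNMAPPED_LOW_SCORE))
            continue
        alignments.append(AlignmentRecord(
            read_id, cid, start, strand,
            tuple((op, n) for op, n in ops if n > 0),
            score, mm, oriented[strand],
        ))
    return alignments, unmapped


# ---------------------------------------------------------------------------
# reference updating
# ---------------------------------------------------------------------------


def _base_counts(
    contigs: dict[str, str], alignments: Iterable[AlignmentRecord]
) -> dict[str, np.ndarray]:
    counts = {cid: np.zeros((len(seq), 4), dtype=np.int32)
              for cid, seq in contigs.items()}
    for aln in alignments:
        mat = counts[aln.contig]
        rpos, qpos = aln.start, 0
        arr = seq_to_array(aln.seq)
        for op, n in aln.ops:
            if op == "M":
                idx = _BASE_IDX[arr[qpos:qpos + n]]
                ok = idx >= 0
                np.add.at(mat, (np.arange(rpos, rpos + n)[ok], idx[ok]), 1)
                rpos += n
                qpos += n
            elif op == "D":
                rpos += n
            else:
                qpos += n
    return counts


def update_reference(
    contigs: dict[str, str],
    alignments: list[AlignmentRecord],
) -> tuple[dict[str, str], list[str]]:
    """Majority-base correction and zero-coverage contig removal.

    At every covered position the emitted base is the strict-majority base
    among covering reads; ties (and uncovered positions) keep the original
    reference base.  Contigs with no mapped reads are dropped and reported.
    """
    counts = _base_counts(contigs, alignments)
    updated: dict[str, str] = {}
    removed: list[str] = []
    for cid, seq in contigs.items():
        mat = counts[cid]
        if mat.sum() == 0:
            removed.append(cid)
            continue
        out = list(seq)
        cov = mat.sum(axis=1)
        for pos in np.nonzero(cov)[0]:
            row = mat[pos]
            mx = row.max()
            winners = np.nonzero(row == mx)[0]
            if len(winners) == 1:
                out[pos] = _IDX_BASE[winners[0]]
        updated[cid] = "".join(out)
    return updated, removed


# ---------------------------------------------------------------------------
# pileups
# ---------------------------------------------------------------------------


class Pileup:
    """Per-species allele counts over reference contigs.

    ``columns[contig][pos]`` maps species -> {base: depth}; adjacent-pair
    counts for dinucleotide analysis are read-phased (a pair increments only
    when one read covers both positions) and computed on demand from the
    retained alignments.
    """

    def __init__(
        self,
        alignments_by_species: dict[str, list[AlignmentRecord]],
        contigs: dict[str, str],
    ) -> None:
        self.species = sorted(alignments_by_species)
        self.reference: dict[str, str | dict[int, str]] = dict(contigs)
        self._alignments = {sp: list(alns)
                            for sp, alns in alignments_by_species.items()}
        self.columns: dict[str, dict[int, dict[str, dict[str, int]]]] = {}
        self._pairs: dict[str, dict[int, dict[str, dict[str, int]]]] = {}
        for sp, alns in alignments_by_species.items():
            for aln in alns:
                if aln.contig not in contigs:
                    raise ValueError(f"alignment to unknown contig {aln.contig}")
                cols = self.columns.setdefault(aln.contig, {})
                rpos, qpos = aln.start, 0
                for op, n in aln.ops:
                    if op == "M":
                        for j in range(n):
                            cnt = (cols.setdefault(rpos + j, {})
                                   .setdefault(sp, {}))
                            b = aln.seq[qpos + j]
                            cnt[b] = cnt.get(b, 0) + 1
                        rpos += n
                        qpos += n
                    elif op == "D":
                        rpos += n
                    else:
                        qpos += n

    @classmethod
    def from_counts(
        cls,
        columns: dict[tuple[str, int], dict[str, dict[str, int]]],
        reference: dict[str, str | dict[int, str]],
        pair_counts: dict[tuple[str, int], dict[str, dict[str, int]]] | None = None,
    ) -> "Pileup":
        """Build a pileup directly from tabulated allele counts.

        For worked examples quoted as printed per-species read counts rather
        than raw reads; ``reference`` may be sparse ({pos: base} per contig).
        """
        self = cls.__new__(cls)
        self.species = sorted({sp for col in columns.values() for sp in col})
        self.reference = dict(reference)
        self._alignments = {}
        self.columns = {}
        self._pairs = {}
        for (cid, pos), col in columns.items():
            self.columns.setdefault(cid, {})[pos] = {
                sp: dict(cnt) for sp, cnt in col.items()
            }
        if pair_counts:
            for (cid, pos), col in pair_counts.items():
                self._pairs.setdefault(cid, {})[pos] = {
                    sp: dict(cnt) for sp, cnt in col.items()
                }
        return self

    # -- accessors ---------------------------------------------------------

    def contigs(self) -> list[str]:
        return sorted(self.columns)

    def positions(self, contig: str) -> list[int]:
        return sorted(self.columns.get(contig, {}))

    def column(self, contig: str, pos: int) -> dict[str, dict[str, int]]:
        return self.columns.get(contig, {}).get(pos, {})

    def depth(self, contig: str, pos: int, species: str) -> int:
        return sum(self.column(contig, pos).get(species, {}).values())

    def ref_base(self, contig: str, pos: int, span: int = 1) -> str | None:
        ref = self.reference.get(contig)
        if ref is None:
            return None
        if isinstance(ref, str):
            return ref[pos:pos + span] if pos + span <= len(ref) else None
        try:
            return "".join(ref[pos + i] for i in range(span))
        except KeyError:
            return None

    def pair_counts(self, contig: str, pos: int) -> dict[str, dict[str, int]]:
        """Read-phased dinucleotide counts at (pos, pos+1), per species."""
        cached = self._pairs.get(contig, {}).get(pos)
        if cached is not None:
            return cached
        out: dict[str, dict[str, int]] = {}
        for sp, alns in self._alignments.items():
            for aln in alns:
                if aln.contig != contig:
                    continue
                if not (aln.start <= pos and pos + 1 < aln.start + aln.ref_span()):
                    continue
                b1 = aln.aligned_base(pos)
                b2 = aln.aligned_base(pos + 1)
                if b1 is None or b2 is None:
                    continue
                cnt = out.setdefault(sp, {})
                cnt[b1 + b2] = cnt.get(b1 + b2, 0) + 1
        self._pairs.setdefault(contig, {})[pos] = out
        return out


def build_pileup(
    alignments_by_species: dict[str, list[AlignmentRecord]],
    contigs: dict[str, str],
) -> Pileup:
    """Per-species pileup over an (updated) contig set."""
    return Pileup(alignments_by_species, contigs)


# ---------------------------------------------------------------------------
# SAM export
# ---------------------------------------------------------------------------


def write_sam(
    path: str,
    alignments: Iterable[AlignmentRecord],
    contigs: dict[str, str],
) -> None:
    """Plain-text SAM export for interoperability (reads are pre-clipped, so
    records are soft-clip free)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for cid, seq in contigs.items():
            fh.write(f"@SQ\tSN:{cid}\tLN:{len(seq)}\n")
        for aln in alignments:
            flag = 16 if aln.strand == "-" else 0
            cigar = "".join(f"{n}{op}" for op, n in aln.ops)
            fh.write(
                f"{aln.read_id}\t{flag}\t{aln.contig}\t{aln.start + 1}\t60\t"
                f"{cigar}\t*\t0\t0\t{aln.seq}\t*\tNM:i:{aln.mismatches}\n"
            )
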