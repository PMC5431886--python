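"""Demultiplexing, restriction-site validation, N filtering and fixed-length
clipping of raw ddRAD read pairs.

The rules are the preprocessing contract of the discovery pipeline: a pair
is kept only when its barcode is non-ambiguous (up to a configurable number
of mismatches, default 1), the residual restriction sites are consistent on
both sides of the fragment (read 1: SphI, read 2: BstYI), neither mate
contains an uncalled base, and both mates are clipped to a fixed 110 bp to
drop low-quality 3' tails.  Filtering is pair-level: if either mate fails,
the pair is discarded with a reason code.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from ._sequtil import hamming, iupac_match
from .simdata import BSTYI, SPHI, ReadPairRecord

REASON_UNMATCHED = "unmatched_barcode"
REASON_AMBIGUOUS = "ambiguous_barcode"
REASON_SITE_R1 = "site_r1"
REASON_SITE_R2 = "site_r2"
REASON_UNCALLED = "uncalled_base"
REASON_TOO_SHORT = "too_short"


@dataclass(frozen=True)
class ReadProcConfig:
    barcode_max_mismatch: int = 1
    clip_length: int = 110
    require_site_both_sides: bool = True
    site_r1: str = SPHI.residual  # "CATGC"
    site_r2: str = BSTYI.residual  # "GATCY"

    def __post_init__(self) -> None:
        if self.barcode_max_mismatch < 0:
            raise ValueError("barcode_max_mismatch must be >= 0")
        if self.clip_length < 1:
            raise ValueError("clip_length must be >= 1")


@dataclass
class DiscardLog:
    """Per-read discard records plus per-reason tallies."""

    records: list[tuple[str, str]] = field(default_factory=list)

    def add(self, read_id: str, reason: str) -> None:
        self.records.append((read_id, reason))

    def counts(self) -> Counter:
        return Counter(reason for _, reason in self.records)

    def __len__(self) -> int:
        return len(self.records)


def demultiplex(
    read_pairs: list[ReadPairRecord],
    barcode_map: dict[str, str],
    config: ReadProcConfig = ReadProcConfig(),
) -> tuple[dict[str, list[ReadPairRecord]], DiscardLog]:
    """Assign pairs to samples by the read-1 barcode prefix.

    A pair is assigned iff exactly one barcode lies within
    ``barcode_max_mismatch`` of the prefix; the barcode is then removed from
    read 1.  Prefixes matching no barcode or more than one are logged as
    unmatched / ambiguous.
    """
    if not barcode_map:
        raise ValueError("barcode map is empty")
    lengths = {len(b) for b in barcode_map.values()}
    if len(lengths) != 1:
        raise ValueError("barcodes must be equal length")
    bc_len = lengths.pop()
    by_sample: dict[str, list[ReadPairRecord]] = {s: [] for s in barcode_map}
    log = DiscardLog()
    for pair in read_pairs:
        prefix = pair.read1[:bc_len]
        hits = [s for s, b in barcode_map.items()
                if hamming(prefix, b) <= config.barcode_max_mismatch]
        if not hits:
            log.add(pair.read_id, REASON_UNMATCHED)
        elif len(hits) > 1:
            log.add(pair.read_id, REASON_AMBIGUOUS)
        else:
            stripped = ReadPairRecord(
                pair.read_id, hits[0],
                pair.read1[bc_len:], pair.qual1[bc_len:],
                pair.read2, pair.qual2, pair.fragment_id,
            )
            by_sample[hits[0]].append(stripped)
    return by_sample, log


def validate_sites(
    pair: ReadPairRecord,
    config: ReadProcConfig = ReadProcConfig(),
) -> tuple[bool, str | None]:
    """Residual restriction sites must be consistent on both fragment sides.

    Pure predicate over a demultiplexed (barcode-stripped) pair: read 1 must
    start with the SphI residual, read 2 with the BstYI residual, matched
    IUPAC-aware.
    """
    if not config.require_site_both_sides:
        return True, None
    if not iupac_match(config.site_r1, pair.read1, 0):
        return False, REASON_SITE_R1
    if not iupac_match(config.site_r2, pair.read2, 0):
        return False, REASON_SITE_R2
    return True, None


def filter_and_clip(
    pairs: list[ReadPairRecord],
    config: ReadProcConfig = ReadProcConfig(),
) -> tuple[list[ReadPairRecord], DiscardLog]:
    """Drop pairs with uncalled bases, then clip both mates to a fixed length.

    The N check runs before clipping (a 3' N is evidence of a bad read even
    if the clip would remove it); reads shorter than the clip length are
    discarded, not padded.  Idempotent on its own output.
    """
    kept: list[ReadPairRecord] = []
    log = DiscardLog()
    n = config.clip_length
    for pair in pairs:
        if "N" in pair.read1 or "N" in pair.read2:
            log.add(pair.read_id, REASON_UNCALLED)
            continue
        if len(pair.read1) < n or len(pair.read2) < n:
            log.add(pair.read_id, REASON_TOO_SHORT)
            continue
        kept.append(ReadPairRecord(
            pair.read_id, pair.sample_id,
            pair.read1[:n], pair.qual1[:n],
            pair.read2[:n], pair.qual2[:n],
            pair.fragment_id,
        ))
    return kept, log


def preprocess(
    read_pairs: list[ReadPairRecord],
    barcode_map: dict[str, str],
    config: ReadProcConfig = ReadProcConfig(),
) -> tuple[dict[str, list[ReadPairRecord]], DiscardLog]:
    """Full preprocessing: demultiplex, site-validate, N-filter, clip.

    Returns per-sample processed pairs and a combined discard log; input
    count is conserved as assigned + discarded.
    """
    by_sample, log = demultiplex(read_pairs, barcode_map, config)
    out: dict[str, list[ReadPairRecord]] = {}
    for sample, pairs in by_sample.items():
        ok_pairs = []
        for pair in pairs:
            ok, reason = validate_sites(pair, config)
            if ok:
                ok_pairs.append(pair)
            else:
                log.add(pair.read_id, reason)
        clipped, clip_log = filter_and_clip(ok_pairs, config)
        log.records.extend(clip_log.records)
        out[sample] = clipped
    return out, log
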