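"""Small nucleotide-sequence helpers shared across the package.

Only plain-ACGT and IUPAC-pattern operations live here; anything heavier
(FASTA/FASTQ I/O, melting temperatures) goes through Biopython.
"""

from __future__ import annotations

import numpy as np

IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPL = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                       "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")

PURINES = frozenset("AG")
BASES = "ACGT"


def complement(seq: str) -> str:
    return seq.translate(_COMPL)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPL)[::-1]


def is_iupac(pattern: str) -> bool:
    return bool(pattern) and all(c in IUPAC for c in pattern)


def iupac_match(pattern: str, text: str, pos: int = 0) -> bool:
    """True iff ``text[pos:pos+len(pattern)]`` matches the IUPAC pattern."""
    if pos < 0 or pos + len(pattern) > len(text):
        return False
    return all(text[pos + i] in IUPAC[p] for i, p in enumerate(pattern))


def find_iupac(pattern: str, seq: str) -> list[int]:
    """All start positions (possibly overlapping) where ``pattern`` matches."""
    n, m = len(seq), len(pattern)
    return [i for i in range(n - m + 1)
            if all(seq[i + j] in IUPAC[p] for j, p in enumerate(pattern))]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def random_dna(rng: np.random.Generator, length: int, gc_fraction: float = 0.5) -> str:
    p_gc = gc_fraction / 2.0
    p_at = (1.0 - gc_fraction) / 2.0
    return "".join(rng.choice(list("ACGT"), size=length,
                              p=[p_at, p_gc, p_gc, p_at]))


def seq_to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
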