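"""IUPAC nucleotide codes and bitmask encodings.

Diploid consensus sequences encode a genotype per site: a plain base for a
homozygote, a two-base ambiguity code for a heterozygote.  Internally every
character maps to a 4-bit allele mask (A=1, C=2, G=4, T=8) so that column
classification and genotype comparison reduce to bitwise operations.
``N`` and ``-`` are both treated as missing data (mask 0).
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"

# two-allele ambiguity codes
AMBIG = {
    frozenset("A"): "A",
    frozenset("C"): "C",
    frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AC"): "M",
    frozenset("AG"): "R",
    frozenset("AT"): "W",
    frozenset("CG"): "S",
    frozenset("CT"): "Y",
    frozenset("GT"): "K",
}

# full code -> allele set (3- and 4-base codes accepted on input)
ALLELES = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "M": frozenset("AC"),
    "R": frozenset("AG"),
    "W": frozenset("AT"),
    "S": frozenset("CG"),
    "Y": frozenset("CT"),
    "K": frozenset("GT"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
}

MISSING = frozenset("N-")
VALID_CHARS = frozenset(ALLELES) | MISSING

_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}

# char ordinal -> allele bitmask; missing and unknown -> 0
MASK_LUT = np.zeros(256, dtype=np.uint8)
for _c, _s in ALLELES.items():
    MASK_LUT[ord(_c)] = sum(_BIT[b] for b in _s)

POPCOUNT = np.array([bin(i).count("1") for i in range(16)], dtype=np.uint8)

_MASK_TO_CHAR = {0: "N"}
for _c, _s in ALLELES.items():
    _MASK_TO_CHAR[int(MASK_LUT[ord(_c)])] = _c


def consensus_char(a: str, b: str) -> str:
    """IUPAC consensus of a diploid genotype (unordered allele pair)."""
    return AMBIG[frozenset((a, b))]


def allele_set(c: str) -> frozenset:
    """Allele set of a consensus character; empty set for N/-."""
    if c in MISSING:
        return frozenset()
    return ALLELES[c]


def encode(seq: str) -> np.ndarray:
    """Sequence -> uint8 allele-bitmask array (0 = missing)."""
    return MASK_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def mask_to_char(mask: int) -> str:
    return _MASK_TO_CHAR[int(mask)]
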