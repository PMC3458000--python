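"""IUPAC nucleotide alphabet: base sets, bitmasks, complements.

Canonical internal form is uppercase DNA: U is normalized to T and the
SILVA terminal-gap character '.' to '-'. Every degenerate symbol maps to
the set of standard bases it denotes; bitmasks (A=1, C=2, G=4, T=8) make
set operations on whole alignments cheap numpy arithmetic.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"

#: IUPAC symbol -> string of standard bases it denotes
IUPAC_SETS: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

#: frozenset of bases -> IUPAC symbol (inverse of IUPAC_SETS)
SET_TO_SYMBOL: dict[frozenset, str] = {
    frozenset(bases): sym for sym, bases in IUPAC_SETS.items()
}

GAP = "-"

#: symbol -> bitmask over bases; gap has the empty mask
MASK: dict[str, int] = {
    sym: sum(1 << BASES.index(b) for b in bases) for sym, bases in IUPAC_SETS.items()
}
MASK[GAP] = 0

_BASE_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: IUPAC-aware complement (R<->Y, K<->M, B<->V, D<->H; S, W, N self)
COMPLEMENT: dict[str, str] = {
    sym: SET_TO_SYMBOL[frozenset(_BASE_COMPLEMENT[b] for b in bases)]
    for sym, bases in IUPAC_SETS.items()
}
COMPLEMENT[GAP] = GAP

# byte-indexed lookup tables for vectorized encoding of sequence arrays
MASK_LUT = np.zeros(256, dtype=np.uint8)
for _sym, _m in MASK.items():
    MASK_LUT[ord(_sym)] = _m

#: base -> 0..3 code; gaps and ambiguity codes -> -1 (treated as missing)
CODE_LUT = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    CODE_LUT[ord(_b)] = _i

_NORMALIZE = str.maketrans("uU.", "TT-")


def normalize(seq: str) -> str:
    """Uppercase, RNA->DNA, '.'->'-'."""
    return seq.upper().translate(_NORMALIZE)


def is_unambiguous(seq: str) -> bool:
    """True if ``seq`` (normalized) contains only A, C, G, T and gaps."""
    return all(c in "ACGT-" for c in seq)


def seq_to_masks(seq: str) -> np.ndarray:
    """Encode a normalized sequence as a uint8 bitmask array."""
    return MASK_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def seq_to_codes(seq: str) -> np.ndarray:
    """Encode a normalized sequence as int8 base codes (-1 = gap/ambiguous)."""
    return CODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
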