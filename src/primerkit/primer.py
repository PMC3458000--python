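"""Degenerate-primer algebra.

A degenerate primer is an IUPAC string in which each position denotes a set
of standard bases. The operations here — expansion into plain sequences,
degeneracy (the product of per-position set sizes), IUPAC-aware reverse
complement, and mismatch counting against aligned target windows — are the
primitives on which primer-site evaluation and refinement are built.

A target position counts as a mismatch when the set of bases it denotes is
not a subset of the primer's set at that position; a gap in the target is
always a mismatch (an indel under a primer disrupts annealing).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from ._alphabet import (
    COMPLEMENT,
    IUPAC_SETS,
    MASK,
    SET_TO_SYMBOL,
    normalize,
    seq_to_masks,
)

VALID_SYMBOLS = frozenset(IUPAC_SETS)

#: number of standard bases each IUPAC symbol denotes
SYMBOL_SIZE = {sym: len(bases) for sym, bases in IUPAC_SETS.items()}


class InvalidPrimerError(ValueError):
    """The sequence is not a valid gap-free IUPAC string."""


@dataclass(frozen=True)
class DegeneratePrimer:
    """A named IUPAC primer.

    Parameters
    ----------
    name : str
        Label such as ``"18S#1"``.
    sequence : str
        IUPAC string over {A,C,G,T,R,Y,S,W,K,M,B,D,H,V,N}; U is accepted
        and normalized to T.
    orientation : {"forward", "reverse_complement"}
    gene : {"18S", "28S", "other"}
    """

    name: str
    sequence: str
    orientation: str = "forward"
    gene: str = "other"

    def __post_init__(self) -> None:
        seq = normalize(self.sequence)
        if not seq:
            raise InvalidPrimerError("primer sequence is empty")
        for i, sym in enumerate(seq):
            if sym not in VALID_SYMBOLS:
                raise InvalidPrimerError(
                    f"invalid IUPAC symbol {sym!r} at position {i + 1} "
                    f"of primer {self.name!r}"
                )
        if self.orientation not in ("forward", "reverse_complement"):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def masks(self) -> np.ndarray:
        """Per-position base-set bitmasks (uint8)."""
        return seq_to_masks(self.sequence)

    # conveniences mirroring the module-level functions
    @property
    def degeneracy(self) -> int:
        return degeneracy(self)

    def expand(self, cap: int = 1024) -> set[str]:
        return expand(self, cap=cap)

    def reverse_complement(self) -> "DegeneratePrimer":
        return reverse_complement(self)

    def with_sequence(self, sequence: str) -> "DegeneratePrimer":
        return replace(self, sequence=sequence)


def _seq_of(primer: "DegeneratePrimer | str") -> str:
    if isinstance(primer, DegeneratePrimer):
        return primer.sequence
    seq = normalize(primer)
    # route through the constructor for validation
    return DegeneratePrimer(name="<anon>", sequence=seq).sequence


def degeneracy(primer: DegeneratePrimer | str) -> int:
    """Product over positions of the number of bases each symbol denotes."""
    seq = _seq_of(primer)
    d = 1
    for sym in seq:
        d *= SYMBOL_SIZE[sym]
    return d


def expand(primer: DegeneratePrimer | str, cap: int = 1024) -> set[str]:
    """All plain ACGT sequences the primer denotes.

    Raises
    ------
    ValueError
        If the degeneracy exceeds ``cap`` (override ``cap`` to force).
    """
    seq = _seq_of(primer)
    d = degeneracy(seq)
    if d > cap:
        raise ValueError(
            f"degeneracy {d} exceeds expansion cap {cap}; "
            f"pass a larger cap to expand anyway"
        )
    return {"".join(combo) for combo in itertools.product(*(IUPAC_SETS[s] for s in seq))}


def reverse_complement(primer: DegeneratePrimer | str) -> DegeneratePrimer | str:
    """IUPAC-aware reverse complement; flips orientation on primer objects."""
    if isinstance(primer, DegeneratePrimer):
        rc_seq = "".join(COMPLEMENT[s] for s in reversed(primer.sequence))
        flipped = (
            "reverse_complement" if primer.orientation == "forward" else "forward"
        )
        return replace(primer, sequence=rc_seq, orientation=flipped)
    seq = _seq_of(primer)
    return "".join(COMPLEMENT[s] for s in reversed(seq))


def count_mismatches(primer: DegeneratePrimer | str, window: str) -> int:
    """Mismatches between a primer and an equal-length aligned target slice.

    A position mismatches when the target symbol's base set is not a subset
    of the primer symbol's base set. A gap ('-' or '.') in the target always
    counts as one mismatch.
    """
    seq = _seq_of(primer)
    win = normalize(window)
    if len(win) != len(seq):
        raise ValueError(
            f"window length {len(win)} != primer length {len(seq)}"
        )
    n = 0
    for p, t in zip(seq, win):
        tm = MASK.get(t, 0)  # unknown target symbols count as mismatches
        if tm == 0 or tm & ~MASK[p]:
            n += 1
    return n


def count_mismatches_matrix(primer: DegeneratePrimer | str, masks: np.ndarray) -> np.ndarray:
    """Vectorized mismatch counts for many aligned slices at once.

    ``masks`` is an (n_sequences, primer_length) uint8 bitmask array
    (see :func:`primerkit._alphabet.seq_to_masks`). Returns per-row counts.
    """
    pm = seq_to_masks(_seq_of(primer))
    if masks.shape[-1] != pm.shape[0]:
        raise ValueError(
            f"window width {masks.shape[-1]} != primer length {pm.shape[0]}"
        )
    mism = (masks & ~pm).astype(bool) | (masks == 0)
    return mism.sum(axis=-1)


def classify_mismatch(n: int) -> str:
    """Bin a mismatch count into the reporting categories.

    Returns ``"zero"``, ``"one"`` or ``"two_plus"``.
    """
    if n < 0:
        raise ValueError("mismatch count must be non-negative")
    if n == 0:
        return "zero"
    if n == 1:
        return "one"
    return "two_plus"


# --------------------------------------------------------------------------
# bundled primer set
# --------------------------------------------------------------------------

_TABLE1_RESOURCE = "table1_primers.tsv"


def load_primer_table(path=None) -> pd.DataFrame:
    """Load a primer set TSV.

    Columns: name, gene, orientation, sequence, pair, printed_degeneracy,
    computed_degeneracy. Without ``path`` the bundled set of sixteen
    18S/28S metazoan rDNA primers is returned. ``printed_degeneracy`` is
    the degeneracy as originally published for the primer pair;
    ``computed_degeneracy`` is the product-rule value (the two disagree
    for one 28S primer, whose published value appears to be a typo).
    """
    import io

    if path is None:
        text = (
            resources.files("primerkit.data").joinpath(_TABLE1_RESOURCE).read_text()
        )
    else:
        text = Path(path).read_text()
    # primer names contain '#', so only whole comment lines are stripped
    lines = [ln for ln in text.splitlines() if not ln.startswith("#")]
    return pd.read_csv(io.StringIO("\n".join(lines)), sep="\t")


def load_primers(path=None) -> dict[str, DegeneratePrimer]:
    """Primer objects keyed by name, from a TSV (bundled set by default)."""
    df = load_primer_table(path)
    return {
        row["name"]: DegeneratePrimer(
            name=row["name"],
            sequence=row["sequence"],
            orientation=row["orientation"],
            gene=str(row["gene"]),
        )
        for _, row in df.iterrows()
    }


def primer_pairs(df: pd.DataFrame | None = None) -> Iterable[tuple[str, str, str]]:
    """Yield (pair_id, forward_sequence, rc_sequence) for pairs where both
    orientations are present in the table."""
    if df is None:
        df = load_primer_table()
    for pair_id, grp in df.groupby("pair", sort=False):
        fwd = grp[grp["orientation"] == "forward"]
        rc = grp[grp["orientation"] == "reverse_complement"]
        if len(fwd) == 1 and len(rc) == 1:
            yield pair_id, fwd["sequence"].iloc[0], rc["sequence"].iloc[0]
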