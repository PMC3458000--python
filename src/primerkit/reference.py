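"""Taxonomically annotated reference alignments: parsing, filtering, subsetting.

The substrate for every scan in this package is a multiple sequence
alignment of rRNA reference sequences in which each record carries a
taxonomy path. The supported on-disk form is aligned FASTA with
SILVA-dialect headers::

    >AANH01015347.5743.7741 Eukaryota;Metazoa;...;Genus species
    CUGGU-UGAU...

where the id token is ``accession.start.stop`` (1-based inclusive span on
the source molecule) and the rest of the header line is a semicolon-
separated taxonomy path. A ``plain`` dialect accepts ordinary FASTA and
attaches empty taxonomy.

Internally residues are uppercase DNA ('U'->'T', '.'->'-'); alignment
columns are 0-based half-open, while reports use 1-based inclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

from ._alphabet import is_unambiguous, normalize, seq_to_codes, seq_to_masks


class FastaParseError(ValueError):
    """A FASTA header could not be parsed under the requested dialect."""


class RaggedAlignmentError(ValueError):
    """Sequences in an alignment differ in length."""


@dataclass(frozen=True)
class TaxonomyPath:
    """Ordered taxonomy labels from root to tip."""

    ranks: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if any(not r for r in self.ranks):
            raise ValueError("taxonomy path contains an empty label")

    @classmethod
    def parse(cls, text: str) -> "TaxonomyPath":
        ranks = tuple(r.strip() for r in text.split(";") if r.strip())
        return cls(ranks)

    def __str__(self) -> str:
        return ";".join(self.ranks)

    def __bool__(self) -> bool:
        return bool(self.ranks)

    def at_depth(self, depth: int) -> str:
        """Label at 0-based depth; raises if the path is shorter."""
        if depth >= len(self.ranks):
            raise IndexError(
                f"taxonomy path {self} has {len(self.ranks)} ranks; "
                f"no rank at depth {depth}"
            )
        return self.ranks[depth]


@dataclass(frozen=True)
class AlignedSequence:
    """One gapped record of a reference alignment."""

    record_id: str
    residues: str
    taxonomy: TaxonomyPath = field(default_factory=TaxonomyPath)
    span_start: int | None = None
    span_stop: int | None = None

    def __post_init__(self) -> None:
        if (
            self.span_start is not None
            and self.span_stop is not None
            and self.span_start > self.span_stop
        ):
            raise ValueError(
                f"{self.record_id}: span start {self.span_start} > stop {self.span_stop}"
            )

    def ungapped(self) -> str:
        return self.residues.replace("-", "")


class ReferenceAlignment:
    """Equal-length gapped sequences with taxonomy.

    Lazily caches two numpy encodings of the residue matrix: IUPAC base-set
    bitmasks (for mismatch counting) and 0..3 base codes with -1 for
    gaps/ambiguity (for diversity statistics).
    """

    def __init__(self, sequences: Sequence[AlignedSequence]):
        sequences = list(sequences)
        if sequences:
            width = len(sequences[0].residues)
            for seq in sequences:
                if len(seq.residues) != width:
                    raise RaggedAlignmentError(
                        f"record {seq.record_id!r} has length "
                        f"{len(seq.residues)}, expected {width}"
                    )
        seen: set[str] = set()
        for seq in sequences:
            if seq.record_id in seen:
                raise ValueError(f"duplicate record id {seq.record_id!r}")
            seen.add(seq.record_id)
        self.sequences: list[AlignedSequence] = sequences
        self._masks: np.ndarray | None = None
        self._codes: np.ndarray | None = None

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self):
        return iter(self.sequences)

    def __getitem__(self, i: int) -> AlignedSequence:
        return self.sequences[i]

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0].residues) if self.sequences else 0

    @property
    def record_ids(self) -> list[str]:
        return [s.record_id for s in self.sequences]

    def masks(self) -> np.ndarray:
        """(n, L) uint8 bitmask matrix (gap = 0)."""
        if self._masks is None:
            if self.sequences:
                self._masks = np.vstack([seq_to_masks(s.residues) for s in self.sequences])
            else:
                self._masks = np.zeros((0, 0), dtype=np.uint8)
        return self._masks

    def codes(self) -> np.ndarray:
        """(n, L) int8 base-code matrix (-1 = gap or ambiguity)."""
        if self._codes is None:
            if self.sequences:
                self._codes = np.vstack([seq_to_codes(s.residues) for s in self.sequences])
            else:
                self._codes = np.zeros((0, 0), dtype=np.int8)
        return self._codes

    def take(self, indices: Iterable[int]) -> "ReferenceAlignment":
        return ReferenceAlignment([self.sequences[i] for i in indices])


# --------------------------------------------------------------------------
# reading and writing
# --------------------------------------------------------------------------

def _parse_silva_title(title: str, lineno: int) -> tuple[str, int, int, TaxonomyPath]:
    parts = title.split(None, 1)
    id_token = parts[0]
    tax_text = parts[1] if len(parts) > 1 else ""
    pieces = id_token.rsplit(".", 2)
    if len(pieces) != 3:
        raise FastaParseError(
            f"line {lineno}: id token {id_token!r} is not accession.start.stop"
        )
    acc, start_s, stop_s = pieces
    try:
        start, stop = int(start_s), int(stop_s)
    except ValueError:
        raise FastaParseError(
            f"line {lineno}: non-numeric span in id token {id_token!r}"
        ) from None
    return acc, start, stop, TaxonomyPath.parse(tax_text)


def read_reference_alignment(
    path: str | Path, header_dialect: str = "silva"
) -> ReferenceAlignment:
    """Read an aligned FASTA file into a :class:`ReferenceAlignment`.

    ``header_dialect="silva"`` parses ``accession.start.stop`` id tokens and
    semicolon taxonomy; ``"plain"`` keeps the whole first header word as the
    record id and attaches an empty taxonomy path.
    """
    if header_dialect not in ("silva", "plain"):
        raise ValueError(f"unknown header dialect {header_dialect!r}")
    path = Path(path)
    with open(path) as fh:
        header_lines = [i + 1 for i, line in enumerate(fh) if line.startswith(">")]
    records: list[AlignedSequence] = []
    with open(path) as fh:
        for lineno, (title, seq) in zip(header_lines, SimpleFastaParser(fh)):
            seq = normalize(seq)
            if header_dialect == "silva":
                acc, start, stop, tax = _parse_silva_title(title, lineno)
                records.append(
                    AlignedSequence(acc, seq, tax, span_start=start, span_stop=stop)
                )
            else:
                rec_id = title.split(None, 1)[0] if title.split() else title
                records.append(AlignedSequence(rec_id, seq))
    try:
        return ReferenceAlignment(records)
    except RaggedAlignmentError as exc:
        raise RaggedAlignmentError(f"{path}: {exc}") from None


def write_reference_alignment(
    aln: ReferenceAlignment, path: str | Path, header_dialect: str = "silva"
) -> None:
    """Write aligned FASTA, reconstructing SILVA-dialect headers."""
    with open(path, "w") as fh:
        for seq in aln:
            if header_dialect == "silva" and seq.span_start is not None:
                header = f"{seq.record_id}.{seq.span_start}.{seq.span_stop}"
            else:
                header = seq.record_id
            if seq.taxonomy:
                header += f" {seq.taxonomy}"
            fh.write(f">{header}\n{seq.residues}\n")


# --------------------------------------------------------------------------
# filtering
# --------------------------------------------------------------------------

def _removal_log(removed: list[tuple[str, str]]) -> pd.DataFrame:
    return pd.DataFrame(removed, columns=["record_id", "reason"])


def filter_ambiguous(
    aln: ReferenceAlignment,
) -> tuple[ReferenceAlignment, pd.DataFrame]:
    """Drop sequences containing any symbol outside {A,C,G,T,-}.

    Returns the filtered alignment and a removal log (record_id, reason).
    """
    keep, removed = [], []
    for i, seq in enumerate(aln):
        if is_unambiguous(seq.residues):
            keep.append(i)
        else:
            removed.append((seq.record_id, "ambiguous_residues"))
    return aln.take(keep), _removal_log(removed)


def drop_allgap_columns(
    aln: ReferenceAlignment,
) -> tuple[ReferenceAlignment, np.ndarray]:
    """Remove columns that are '-' in every sequence.

    Returns the trimmed alignment and an old->new column index map
    (length = old n_columns; dropped columns map to -1).
    """
    if len(aln) == 0:
        return aln, np.zeros(0, dtype=int)
    gap_matrix = aln.masks() == 0
    all_gap = gap_matrix.all(axis=0)
    index_map = np.full(aln.n_columns, -1, dtype=int)
    kept = np.flatnonzero(~all_gap)
    index_map[kept] = np.arange(kept.size)
    if all_gap.any():
        new_records = [
            replace(s, residues="".join(s.residues[j] for j in kept)) for s in aln
        ]
        return ReferenceAlignment(new_records), index_map
    return aln, index_map


def screen_span(
    aln: ReferenceAlignment, sites: Sequence[tuple[int, int]]
) -> tuple[ReferenceAlignment, pd.DataFrame]:
    """Keep only sequences whose read spans every site interval.

    A sequence spans a half-open column interval ``[a, b)`` when it has at
    least one non-gap residue at or before column ``a`` and at or after
    column ``b - 1`` — i.e. the sequenced region covers the whole site, so
    primer-site slices reflect real data rather than missing ends.
    """
    if not sites:
        raise ValueError("screen_span requires at least one site interval")
    for a, b in sites:
        if not (0 <= a < b <= aln.n_columns):
            raise ValueError(
                f"site interval [{a}, {b}) outside alignment of width {aln.n_columns}"
            )
    first_req = min(a for a, _ in sites)
    last_req = max(b for _, b in sites) - 1
    keep, removed = [], []
    for i, seq in enumerate(aln):
        nongap = np.flatnonzero(aln.masks()[i] != 0)
        if nongap.size and nongap[0] <= first_req and nongap[-1] >= last_req:
            keep.append(i)
        else:
            removed.append((seq.record_id, "does_not_span_sites"))
    return aln.take(keep), _removal_log(removed)


# --------------------------------------------------------------------------
# taxonomy
# --------------------------------------------------------------------------

def load_phylum_names() -> list[str]:
    """Bundled metazoan phylum names, in report order."""
    with resources.files("primerkit.data").joinpath("metazoan_phyla.txt").open() as fh:
        return [line.strip() for line in fh if line.strip() and not line.startswith("#")]


_PHYLUM_SET: frozenset[str] | None = None


def phylum_of(taxonomy: TaxonomyPath, depth: int | None = None) -> str | None:
    """Extract the phylum label from a taxonomy path.

    With ``depth`` given, returns the label at that 0-based depth. Otherwise
    matches path labels (deepest first) against the bundled metazoan phylum
    list; if none matches, falls back to the terminal label. Returns None
    for an empty path.
    """
    if not taxonomy:
        return None
    if depth is not None:
        return taxonomy.at_depth(depth)
    global _PHYLUM_SET
    if _PHYLUM_SET is None:
        _PHYLUM_SET = frozenset(load_phylum_names())
    for label in reversed(taxonomy.ranks):
        if label in _PHYLUM_SET:
            return label
    return taxonomy.ranks[-1]


def subset_by_taxon(
    aln: ReferenceAlignment, label: str, rank_depth: int | None = None
) -> ReferenceAlignment:
    """Records whose taxonomy matches ``label``.

    With ``rank_depth`` the match is at that exact depth (paths too short
    never match); without it, any rank may match. An absent label yields an
    empty alignment with a warning rather than an error.
    """
    keep = []
    for i, seq in enumerate(aln):
        ranks = seq.taxonomy.ranks
        if rank_depth is not None:
            if len(ranks) > rank_depth and ranks[rank_depth] == label:
                keep.append(i)
        elif label in ranks:
            keep.append(i)
    if not keep:
        warnings.warn(f"taxon label {label!r} matched no records", stacklevel=2)
    return aln.take(keep)
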