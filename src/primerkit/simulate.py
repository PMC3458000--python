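"""Synthetic reference alignments with planted structure.

The generator emulates a filtered rRNA reference alignment: blocks of
conserved columns (fixed or IUPAC motifs, where primers sit) alternate
with variable blocks whose per-site diversity is controlled exactly, and
every sequence carries a taxonomy path ending in a phylum label. Ground
truth (block coordinates and motifs) is returned alongside, so conserved-
region discovery, mismatch profiling, refinement, and amplicon prediction
can all be checked against known answers without any reference database.

Per variable column the base frequencies follow a symmetric minor-allele
model: one major base at frequency p and the other three at (1-p)/3 each,
with p solving 1 - p^2 - (1-p)^2/3 = d so that the expected per-site
heterozygosity — and hence expected pairwise pi — equals the target
diversity d (feasible for d in [0, 0.75]).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence, Union

import numpy as np
import pandas as pd

from ._alphabet import BASES, IUPAC_SETS
from .compatibility import PrimerSite
from .reference import AlignedSequence, ReferenceAlignment, TaxonomyPath


@dataclass(frozen=True)
class ConservedBlock:
    """A fixed or IUPAC motif emitted identically (up to IUPAC draws) in
    every sequence; the planted footprint of a primer site."""

    motif: str
    name: str = ""

    @property
    def length(self) -> int:
        return len(self.motif)


@dataclass(frozen=True)
class VariableBlock:
    """Columns with a target per-site diversity."""

    length: int
    diversity: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.diversity <= 0.75):
            raise ValueError(
                f"diversity target {self.diversity} infeasible; the symmetric "
                "minor-allele model covers [0, 0.75]"
            )


Block = Union[ConservedBlock, VariableBlock]


@dataclass(frozen=True)
class SyntheticModel:
    """Layout shared by all phyla: an ordered list of blocks."""

    phyla: tuple[tuple[str, int], ...]
    blocks: tuple[Block, ...]
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.phyla:
            raise ValueError("model needs at least one phylum")
        for label, n in self.phyla:
            if n < 1:
                raise ValueError(f"phylum {label!r} needs n >= 1")
        if not (0.0 <= self.indel_rate < 1.0):
            raise ValueError("indel_rate must be in [0, 1)")

    @property
    def n_sequences(self) -> int:
        return sum(n for _, n in self.phyla)

    @property
    def n_columns(self) -> int:
        return sum(b.length for b in self.blocks)


def _major_freq(diversity: float) -> float:
    # invert 1 - p^2 - (1-p)^2/3 = d on p in [1/4, 1]
    return (1.0 + math.sqrt(9.0 - 12.0 * diversity)) / 4.0


def generate_reference(
    model: SyntheticModel,
) -> tuple[ReferenceAlignment, pd.DataFrame]:
    """Draw an alignment from the model; deterministic for a given seed.

    Returns the alignment and a ground-truth frame with one row per block:
    kind, start, stop (0-based half-open columns), motif, diversity.
    """
    rng = np.random.default_rng(model.seed)
    n = model.n_sequences
    columns: list[np.ndarray] = []
    truth_rows = []
    cursor = 0
    for bi, block in enumerate(model.blocks):
        if isinstance(block, ConservedBlock):
            for sym in block.motif.upper().replace("U", "T"):
                choices = IUPAC_SETS[sym]
                if len(choices) == 1:
                    col = np.full(n, choices, dtype="U1")
                else:
                    col = rng.choice(list(choices), size=n)
                columns.append(col)
            truth_rows.append(
                {
                    "block": bi,
                    "kind": "conserved",
                    "start": cursor,
                    "stop": cursor + block.length,
                    "motif": block.motif,
                    "diversity": 0.0,
                    "name": block.name,
                }
            )
        else:
            p = _major_freq(block.diversity)
            minor = (1.0 - p) / 3.0
            for _ in range(block.length):
                major = rng.integers(4)
                freqs = np.full(4, minor)
                freqs[major] = p
                col = rng.choice(list(BASES), size=n, p=freqs)
                if model.indel_rate > 0:
                    gaps = rng.random(n) < model.indel_rate
                    col = np.where(gaps, "-", col)
                columns.append(col)
            truth_rows.append(
                {
                    "block": bi,
                    "kind": "variable",
                    "start": cursor,
                    "stop": cursor + block.length,
                    "motif": "",
                    "diversity": block.diversity,
                    "name": "",
                }
            )
        cursor += block.length
    matrix = np.stack(columns, axis=1) if columns else np.zeros((n, 0), dtype="U1")
    records = []
    i = 0
    for label, n_phy in model.phyla:
        for _ in range(n_phy):
            residues = "".join(matrix[i])
            ungapped_len = len(residues) - residues.count("-")
            records.append(
                AlignedSequence(
                    record_id=f"SYN{i:06d}",
                    residues=residues,
                    taxonomy=TaxonomyPath(("Eukaryota", "Metazoa", label)),
                    span_start=1,
                    span_stop=max(ungapped_len, 1),
                )
            )
            i += 1
    truth = pd.DataFrame(
        truth_rows,
        columns=["block", "kind", "start", "stop", "motif", "diversity", "name"],
    )
    return ReferenceAlignment(records), truth


def plant_mismatches(
    aln: ReferenceAlignment,
    site: PrimerSite | tuple[int, int],
    phylum: str,
    fraction: float,
    position: int,
    base: str,
) -> ReferenceAlignment:
    """Mutate ``round(fraction * n)`` sequences of one phylum at a single
    primer position, planting a shared variant for refinement tests.

    ``position`` is 0-based within the site; the first qualifying sequences
    in alignment order are mutated (deterministic).
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    start = site.start if isinstance(site, PrimerSite) else site[0]
    stop = site.stop if isinstance(site, PrimerSite) else site[1]
    if not (0 <= start + position < stop):
        raise ValueError(f"position {position} outside site [{start}, {stop})")
    base = base.upper()
    if base not in BASES:
        raise ValueError(f"base must be one of {BASES}, got {base!r}")
    members = [
        i for i, s in enumerate(aln) if phylum in s.taxonomy.ranks
    ]
    if not members:
        raise ValueError(f"phylum {phylum!r} not present in alignment")
    k = int(round(fraction * len(members)))
    col = start + position
    new_records = list(aln.sequences)
    for i in members[:k]:
        seq = new_records[i]
        residues = seq.residues[:col] + base + seq.residues[col + 1 :]
        new_records[i] = replace(seq, residues=residues)
    return ReferenceAlignment(new_records)


def model_from_dict(cfg: dict) -> SyntheticModel:
    """Build a model from a parsed config mapping (e.g. TOML).

    Expected keys: ``seed``, ``indel_rate``, ``phyla`` (list of
    ``{label, n}``) and ``blocks`` (list of ``{kind: conserved, motif}`` or
    ``{kind: variable, length, diversity}``).
    """
    phyla = tuple((p["label"], int(p["n"])) for p in cfg.get("phyla", []))
    blocks: list[Block] = []
    for b in cfg.get("blocks", []):
        kind = b.get("kind", "variable")
        if kind == "conserved":
            blocks.append(ConservedBlock(motif=b["motif"], name=b.get("name", "")))
        elif kind == "variable":
            blocks.append(
                VariableBlock(
                    length=int(b["length"]),
                    diversity=float(b.get("diversity", 0.0)),
                )
            )
        else:
            raise ValueError(f"unknown block kind {kind!r}")
    return SyntheticModel(
        phyla=phyla,
        blocks=tuple(blocks),
        indel_rate=float(cfg.get("indel_rate", 0.0)),
        seed=int(cfg.get("seed", 0)),
    )
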