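"""Conserved-site discovery, consensus primers, and degeneracy refinement.

Candidate primer sites are maximal runs of well-conserved, gap-poor
alignment columns. A degenerate consensus primer is read off such a region
by covering, at each column, every base above a frequency threshold with
the smallest IUPAC code.

Refinement then makes the primer universal across phyla: for any phylum in
which more than 20% of sequences carry at least one mismatch under the
primer, the mismatching target bases are inspected position by position;
if a single offending base at a single position is shared by more than 20%
of that phylum's sequences, it is added to the primer's IUPAC code there,
the site is re-localized, and the scan repeats. The loop stops when every
phylum with more than ``taxa_min_n`` sequences is below the flag threshold
(converged), or when no single-site fix qualifies — mismatches spread
thinly over several positions cannot be repaired without inflating
degeneracy past what PCR tolerates, so those phyla are reported unresolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._alphabet import BASES, IUPAC_SETS, SET_TO_SYMBOL
from .compatibility import PrimerSite, locate_primer_site
from .primer import DegeneratePrimer, count_mismatches_matrix, degeneracy
from .reference import ReferenceAlignment, phylum_of


@dataclass(frozen=True)
class CandidateRegion:
    """A run of conserved columns suitable for primer placement."""

    start: int
    stop: int
    min_conservation: float

    @property
    def columns(self) -> tuple[int, int]:
        return (self.start, self.stop)

    @property
    def length(self) -> int:
        return self.stop - self.start


def conservation_profile(aln: ReferenceAlignment) -> np.ndarray:
    """Per-column frequency of the modal non-gap base among non-gap residues.

    All-gap columns score 0.
    """
    codes = aln.codes()
    n_cols = aln.n_columns
    counts = np.zeros((4, n_cols), dtype=np.int64)
    for b in range(4):
        counts[b] = (codes == b).sum(axis=0)
    nongap = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cons = np.where(nongap > 0, counts.max(axis=0) / np.maximum(nongap, 1), 0.0)
    return cons


def column_conservation(aln: ReferenceAlignment, column: int) -> float:
    """Conservation of a single column (see :func:`conservation_profile`)."""
    if not (0 <= column < aln.n_columns):
        raise IndexError(f"column {column} outside alignment of width {aln.n_columns}")
    return float(conservation_profile(aln)[column])


def gap_fraction_profile(aln: ReferenceAlignment) -> np.ndarray:
    """Per-column fraction of sequences with a gap."""
    return (aln.masks() == 0).mean(axis=0)


def find_conserved_regions(
    aln: ReferenceAlignment,
    min_len: int = 18,
    threshold: float = 0.85,
    max_gap_fraction: float = 0.1,
) -> list[CandidateRegion]:
    """Maximal runs of >= ``min_len`` consecutive columns that are both
    conserved (modal-base frequency >= ``threshold``) and gap-poor
    (gap fraction <= ``max_gap_fraction``), sorted by start column."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    cons = conservation_profile(aln)
    good = (cons >= threshold) & (gap_fraction_profile(aln) <= max_gap_fraction)
    regions: list[CandidateRegion] = []
    start = None
    for i, ok in enumerate(np.append(good, False)):
        if ok and start is None:
            start = i
        elif not ok and start is not None:
            if i - start >= min_len:
                regions.append(
                    CandidateRegion(start, i, float(cons[start:i].min()))
                )
            start = None
    return regions


def consensus_primer(
    aln: ReferenceAlignment,
    region: CandidateRegion | tuple[int, int],
    include_threshold: float = 0.2,
    name: str = "consensus",
    gene: str = "other",
) -> DegeneratePrimer:
    """Degenerate consensus over a region.

    Per column, the IUPAC code covering every base whose frequency among
    non-gap residues is >= ``include_threshold``; the modal base is always
    included. At ``include_threshold=0`` this is the minimal IUPAC cover of
    all observed bases.
    """
    start, stop = region.columns if isinstance(region, CandidateRegion) else region
    if not (0 <= start < stop <= aln.n_columns):
        raise ValueError(f"region [{start}, {stop}) outside alignment")
    codes = aln.codes()[:, start:stop]
    symbols = []
    for j in range(stop - start):
        col = codes[:, j]
        col = col[col >= 0]
        if col.size == 0:
            raise ValueError(
                f"column {start + j + 1} is entirely gaps; "
                "drop all-gap columns before building a consensus"
            )
        freqs = np.bincount(col, minlength=4) / col.size
        included = {
            BASES[b]
            for b in range(4)
            if freqs[b] >= include_threshold and freqs[b] > 0
        }
        included.add(BASES[int(np.argmax(freqs))])
        symbols.append(SET_TO_SYMBOL[frozenset(included)])
    return DegeneratePrimer(name=name, sequence="".join(symbols), gene=gene)


# --------------------------------------------------------------------------
# refinement
# --------------------------------------------------------------------------

@dataclass
class RefinementConfig:
    """Thresholds of the iterative degeneracy-refinement rule.

    flag_threshold
        A phylum is flagged when the fraction of its sequences with >=1
        mismatch exceeds this (default 0.20).
    site_share_threshold
        A (position, base) fix qualifies when the offending base is shared
        by more than this fraction of the flagged phylum (default 0.20).
    taxa_min_n
        Only phyla with more than this many sequences count (default 10).
    degeneracy_cap
        Refinement never pushes primer degeneracy above this; overly
        degenerate primers fail to amplify in practice (default 64).
    max_iter
        Hard stop on refinement iterations.
    """

    flag_threshold: float = 0.20
    site_share_threshold: float = 0.20
    taxa_min_n: int = 10
    degeneracy_cap: int = 64
    max_iter: int = 100

    def __post_init__(self) -> None:
        for attr in ("flag_threshold", "site_share_threshold"):
            v = getattr(self, attr)
            if not (0 < v <= 1):
                raise ValueError(f"{attr} must be in (0, 1], got {v}")
        if self.degeneracy_cap < 1:
            raise ValueError("degeneracy_cap must be >= 1")


@dataclass
class RefinementIteration:
    iteration: int
    primer_sequence: str
    site: PrimerSite
    prevalence: dict[str, float]  # >=1-mismatch fraction per eligible phylum
    flagged: list[str]
    added: tuple[int, str] | None  # (0-based primer position, base) or None


@dataclass
class RefinementAudit:
    """Trace of a refinement run."""

    iterations: list[RefinementIteration] = field(default_factory=list)
    converged: bool = False
    unresolved_phyla: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for it in self.iterations:
            for phylum, prev in sorted(it.prevalence.items()):
                rows.append(
                    {
                        "iteration": it.iteration,
                        "primer": it.primer_sequence,
                        "site_start": it.site.start + 1,
                        "site_stop": it.site.stop,
                        "phylum": phylum,
                        "mismatch_prevalence": prev,
                        "flagged": phylum in it.flagged,
                        "added": (
                            f"{it.added[0] + 1}:{it.added[1]}" if it.added else ""
                        ),
                    }
                )
        return pd.DataFrame(rows)


def _group_indices(
    aln: ReferenceAlignment, rank: int | str
) -> dict[str, np.ndarray]:
    depth = None if rank == "phylum" else int(rank)
    groups: dict[str, list[int]] = {}
    for i, seq in enumerate(aln):
        label = phylum_of(seq.taxonomy, depth=depth) or "<unclassified>"
        groups.setdefault(label, []).append(i)
    return {k: np.asarray(v) for k, v in groups.items()}


def refine_primer(
    aln: ReferenceAlignment,
    primer: DegeneratePrimer,
    site: PrimerSite | tuple[int, int],
    cfg: RefinementConfig | None = None,
    rank: int | str = "phylum",
    relocate: bool = True,
) -> tuple[DegeneratePrimer, RefinementAudit]:
    """Iteratively widen the primer's IUPAC codes until every large phylum
    is below the mismatch-prevalence threshold.

    Per iteration at most one (position, base) is added — the one with the
    highest within-phylum sharing fraction, ties going to the 5'-most
    position then alphabetical base — and the site is re-localized before
    re-profiling (``relocate=False`` pins the site, for pre-aligned fixed
    windows). Exhausting the degeneracy cap or the iteration budget is not
    an error; the audit reports ``converged=False`` with the phyla left
    unresolved.
    """
    cfg = cfg or RefinementConfig()
    if not isinstance(site, PrimerSite):
        site = PrimerSite(site[0], site[1])
    if site.width != len(primer):
        raise ValueError(
            f"site width {site.width} != primer length {len(primer)}"
        )
    groups = _group_indices(aln, rank)
    eligible = {k: idx for k, idx in groups.items() if idx.size > cfg.taxa_min_n}
    audit = RefinementAudit()
    current = primer

    for iteration in range(cfg.max_iter + 1):
        masks = aln.masks()[:, site.start : site.stop]
        mm = count_mismatches_matrix(current, masks)
        prevalence = {
            k: float((mm[idx] >= 1).mean()) for k, idx in eligible.items()
        }
        flagged = sorted(
            k for k, p in prevalence.items() if p > cfg.flag_threshold
        )
        record = RefinementIteration(
            iteration, current.sequence, site, prevalence, flagged, None
        )
        if not flagged:
            audit.iterations.append(record)
            audit.converged = True
            return current, audit
        if iteration == cfg.max_iter:
            audit.iterations.append(record)
            audit.unresolved_phyla = flagged
            return current, audit

        # best single-site fix across all flagged phyla
        pmasks = current.masks
        best: tuple[float, int, str] | None = None  # (share, pos, base)
        for phylum in flagged:
            sub = masks[eligible[phylum]]
            n_phy = sub.shape[0]
            for pos in range(len(current)):
                for b, base in enumerate(BASES):
                    bit = 1 << b
                    if pmasks[pos] & bit:
                        continue  # base already allowed
                    share = float((sub[:, pos] == bit).sum()) / n_phy
                    if share > cfg.site_share_threshold:
                        if (
                            best is None
                            or share > best[0]
                            or (share == best[0] and (pos, base) < (best[1], best[2]))
                        ):
                            best = (share, pos, base)
        if best is None:
            audit.iterations.append(record)
            audit.unresolved_phyla = flagged
            return current, audit

        _, pos, base = best
        new_set = frozenset(IUPAC_SETS[current.sequence[pos]]) | {base}
        new_seq = (
            current.sequence[:pos]
            + SET_TO_SYMBOL[new_set]
            + current.sequence[pos + 1 :]
        )
        if degeneracy(new_seq) > cfg.degeneracy_cap:
            audit.iterations.append(record)
            audit.unresolved_phyla = flagged
            return current, audit

        record.added = (pos, base)
        audit.iterations.append(record)
        current = current.with_sequence(new_seq)
        if relocate:
            site = locate_primer_site(aln, current)

    raise AssertionError("unreachable")  # pragma: no cover
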