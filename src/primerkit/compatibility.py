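"""Primer-site localization and per-taxon mismatch profiling.

Given a primer and a reference alignment, locate the alignment window that
the primer targets (the window minimizing total mismatches over all
sequences) and tabulate, per phylum, how many sequences carry zero, one, or
two-or-more mismatches under the primer. One- and two-or-more-mismatch
percentages are tallied independently per phylum, the standard layout for
reporting taxonomic primer coverage.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .primer import DegeneratePrimer, count_mismatches_matrix, reverse_complement
from .reference import ReferenceAlignment, load_phylum_names, phylum_of


@dataclass(frozen=True)
class PrimerSite:
    """A primer's window on an alignment: 0-based half-open columns."""

    start: int
    stop: int
    strand: str = "plus"  # {"plus", "minus"}
    total_mismatch_score: int = 0

    @property
    def columns(self) -> tuple[int, int]:
        return (self.start, self.stop)

    @property
    def width(self) -> int:
        return self.stop - self.start


def _window_scores(aln: ReferenceAlignment, primer: DegeneratePrimer) -> np.ndarray:
    """Total mismatch count per column offset, summed over sequences."""
    masks = aln.masks()
    k = len(primer)
    n_offsets = aln.n_columns - k + 1
    scores = np.empty(n_offsets, dtype=np.int64)
    for o in range(n_offsets):
        scores[o] = count_mismatches_matrix(primer, masks[:, o : o + k]).sum()
    return scores


def locate_primer_site(
    aln: ReferenceAlignment,
    primer: DegeneratePrimer,
    search_both_strands: bool = False,
) -> PrimerSite:
    """Best-scoring window for the primer over all column offsets.

    Ties are broken leftmost; with ``search_both_strands`` the reverse
    complement of the primer is scored against the same rows and the plus
    strand wins ties.
    """
    if len(aln) == 0:
        raise ValueError("cannot locate a primer site on an empty alignment")
    if aln.n_columns < len(primer):
        raise ValueError(
            f"alignment width {aln.n_columns} shorter than primer length {len(primer)}"
        )
    plus = _window_scores(aln, primer)
    best_o = int(np.argmin(plus))
    best = PrimerSite(best_o, best_o + len(primer), "plus", int(plus[best_o]))
    if search_both_strands:
        minus = _window_scores(aln, reverse_complement(primer))
        o = int(np.argmin(minus))
        if minus[o] < best.total_mismatch_score:
            best = PrimerSite(o, o + len(primer), "minus", int(minus[o]))
    return best


@dataclass
class MismatchProfile:
    """Per-taxon 0/1/2+ mismatch tallies for one primer at one site.

    ``table`` columns: taxon, n, zero, one, two_plus, one_pct, two_plus_pct
    (percentages on the 0-100 scale).
    """

    primer_name: str
    site: PrimerSite
    table: pd.DataFrame

    def prevalence(self) -> pd.Series:
        """Fraction of each taxon's sequences with >=1 mismatch (0-1 scale)."""
        t = self.table.set_index("taxon")
        return (t["one"] + t["two_plus"]) / t["n"]


def _taxon_order(labels: list[str], order: list[str] | None) -> list[str]:
    if order is None:
        order = load_phylum_names()
    ranked = [t for t in order if t in labels]
    extras = sorted(set(labels) - set(ranked))
    return ranked + extras


def profile_mismatches(
    aln: ReferenceAlignment,
    primer: DegeneratePrimer,
    site: PrimerSite,
    rank: int | str = "phylum",
    taxon_order: list[str] | None = None,
) -> MismatchProfile:
    """Tally 0 / 1 / >=2 mismatch sequences per taxon at a primer site.

    ``rank`` is either ``"phylum"`` (label matched against the bundled
    phylum list) or an integer taxonomy depth. Sequences with no taxonomy
    are grouped under ``"<unclassified>"``. A site slice that is entirely
    gaps scores one mismatch per column and so lands in the two-or-more
    class for any primer of length >=2.
    """
    effective = primer if site.strand == "plus" else reverse_complement(primer)
    counts = count_mismatches_matrix(
        effective, aln.masks()[:, site.start : site.stop]
    )
    depth = None if rank == "phylum" else int(rank)
    taxa = [
        phylum_of(seq.taxonomy, depth=depth) or "<unclassified>" for seq in aln
    ]
    df = pd.DataFrame({"taxon": taxa, "mm": counts})
    rows = []
    for taxon, grp in df.groupby("taxon", sort=False):
        n = len(grp)
        zero = int((grp["mm"] == 0).sum())
        one = int((grp["mm"] == 1).sum())
        two_plus = n - zero - one
        rows.append(
            {
                "taxon": taxon,
                "n": n,
                "zero": zero,
                "one": one,
                "two_plus": two_plus,
                "one_pct": 100.0 * one / n,
                "two_plus_pct": 100.0 * two_plus / n,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["taxon", "n", "zero", "one", "two_plus", "one_pct", "two_plus_pct"],
    )
    if len(table):
        order = _taxon_order(list(table["taxon"]), taxon_order)
        table = (
            table.set_index("taxon").loc[order].reset_index()
        )
    return MismatchProfile(primer.name, site, table)


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

def _cell(pct: float, count: int) -> str:
    return f"{pct:.2f} ({count})"


def render_profile_table(profiles: list[MismatchProfile]) -> str:
    """Render per-taxon mismatch profiles as a TSV table.

    One row per taxon (``"Taxon (n)"``); per primer two columns, One and
    Two or more, each cell ``"P.PP (c)"`` — percentage to two decimals with
    the sequence count in parentheses.
    """
    header = ["Taxon"]
    for p in profiles:
        header += [f"{p.primer_name} One", f"{p.primer_name} Two or more"]
    lines = ["\t".join(header)]
    if not profiles:
        return lines[0] + "\n"
    taxa = list(profiles[0].table["taxon"])
    indexed = [p.table.set_index("taxon") for p in profiles]
    for t in indexed[1:]:
        if list(t.index) != taxa:
            raise ValueError("profiles do not share a common taxon universe")
    for taxon in taxa:
        n = int(indexed[0].loc[taxon, "n"])
        row = [f"{taxon} ({n})"]
        for t in indexed:
            r = t.loc[taxon]
            row.append(_cell(r["one_pct"], int(r["one"])))
            row.append(_cell(r["two_plus_pct"], int(r["two_plus"])))
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


_CELL_RE = re.compile(r"^([\d.]+) \((\d+)\)$")
_TAXON_RE = re.compile(r"^(.*) \((\d+)\)$")


def parse_profile_table(text: str) -> pd.DataFrame:
    """Parse a table produced by :func:`render_profile_table` back into
    long form (taxon, n, primer, one, two_plus)."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    primers = [h[: -len(" One")] for h in header[1::2]]
    rows = []
    for line in lines[1:]:
        cells = line.split("\t")
        m = _TAXON_RE.match(cells[0])
        if not m:
            raise ValueError(f"malformed taxon cell {cells[0]!r}")
        taxon, n = m.group(1), int(m.group(2))
        for j, primer in enumerate(primers):
            one = _CELL_RE.match(cells[1 + 2 * j])
            two = _CELL_RE.match(cells[2 + 2 * j])
            if not one or not two:
                raise ValueError(f"malformed cell in row {taxon!r}")
            rows.append(
                {
                    "taxon": taxon,
                    "n": n,
                    "primer": primer,
                    "one": int(one.group(2)),
                    "two_plus": int(two.group(2)),
                }
            )
    return pd.DataFrame(rows)
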