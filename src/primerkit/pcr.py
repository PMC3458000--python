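"""In-silico PCR: amplicon prediction on unaligned template sequences.

A forward primer hit and a downstream reverse-primer hit on the same
template delimit the predicted product. The reverse primer is supplied in
its oligo (reverse-complement) orientation, as printed on an order sheet;
its plus-strand target is recovered internally by reverse complementation.
Amplicon length spans from the forward primer's 5' end through the reverse
primer's 5' end on the opposite strand, i.e. it includes both primers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._alphabet import normalize, seq_to_masks
from .primer import DegeneratePrimer, count_mismatches_matrix, reverse_complement

DEFAULT_MAX_LENGTH = 5000


@dataclass(frozen=True)
class AmpliconPrediction:
    """One predicted product: 0-based half-open template coordinates."""

    template_id: str
    fwd_start: int
    rev_end: int
    fwd_mismatches: int
    rev_mismatches: int

    @property
    def length(self) -> int:
        return self.rev_end - self.fwd_start

    @property
    def total_mismatches(self) -> int:
        return self.fwd_mismatches + self.rev_mismatches


def _primer_hits(
    template_masks: np.ndarray, primer: DegeneratePrimer, max_mismatch: int
) -> list[tuple[int, int]]:
    """(start, mismatches) for every window within the mismatch budget."""
    k = len(primer)
    L = template_masks.shape[0]
    if L < k:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(template_masks, k)
    counts = count_mismatches_matrix(primer, windows)
    return [(int(i), int(c)) for i, c in enumerate(counts) if c <= max_mismatch]


def predict_amplicons(
    template: str,
    fwd: DegeneratePrimer,
    rev: DegeneratePrimer,
    max_mismatch: int = 2,
    max_length: int = DEFAULT_MAX_LENGTH,
    template_id: str = "",
) -> list[AmpliconPrediction]:
    """Every valid forward/reverse pairing on the plus strand, best first.

    Pairings are ordered by (total mismatches, product length, leftmost
    forward start). The template must be gap-free; the reverse primer is
    given in oligo orientation.
    """
    seq = normalize(template)
    if "-" in seq:
        raise ValueError("template must be gap-free (unaligned)")
    if len(fwd) > len(seq) or len(rev) > len(seq):
        warnings.warn(
            f"primer longer than template {template_id or '<anon>'}", stacklevel=2
        )
        return []
    masks = seq_to_masks(seq)
    rev_target = reverse_complement(rev)  # plus-strand footprint of the reverse site
    fwd_hits = _primer_hits(masks, fwd, max_mismatch)
    rev_hits = _primer_hits(masks, rev_target, max_mismatch)
    products = []
    for f_start, f_mm in fwd_hits:
        f_end = f_start + len(fwd)
        for r_start, r_mm in rev_hits:
            r_end = r_start + len(rev)
            if r_start >= f_end and r_end - f_start <= max_length:
                products.append(
                    AmpliconPrediction(template_id, f_start, r_end, f_mm, r_mm)
                )
    products.sort(key=lambda p: (p.total_mismatches, p.length, p.fwd_start))
    return products


def predict_amplicon(
    template: str,
    fwd: DegeneratePrimer,
    rev: DegeneratePrimer,
    max_mismatch: int = 2,
    max_length: int = DEFAULT_MAX_LENGTH,
    template_id: str = "",
) -> AmpliconPrediction | None:
    """Best single product (fewest mismatches, then shortest, then leftmost),
    or None when no pairing fits the mismatch budget."""
    products = predict_amplicons(
        template, fwd, rev, max_mismatch, max_length, template_id
    )
    return products[0] if products else None


def amplicon_length_summary(
    templates: Mapping[str, str] | Iterable[tuple[str, str]],
    fwd: DegeneratePrimer,
    rev: DegeneratePrimer,
    max_mismatch: int = 2,
    max_length: int = DEFAULT_MAX_LENGTH,
) -> tuple[pd.DataFrame, dict]:
    """Per-template predictions plus a length summary.

    Returns a frame (template_id, fwd_start, rev_end, length, fwd_mm,
    rev_mm; NaN rows for templates without a product) and a summary dict
    with min/median/max product length and the hit rate (fraction of
    templates yielding a product).
    """
    items = templates.items() if isinstance(templates, Mapping) else templates
    rows = []
    lengths = []
    n = 0
    for template_id, seq in items:
        n += 1
        pred = predict_amplicon(
            seq, fwd, rev, max_mismatch, max_length, template_id
        )
        if pred is None:
            rows.append(
                {
                    "template_id": template_id,
                    "fwd_start": np.nan,
                    "rev_end": np.nan,
                    "length": np.nan,
                    "fwd_mm": np.nan,
                    "rev_mm": np.nan,
                }
            )
        else:
            lengths.append(pred.length)
            rows.append(
                {
                    "template_id": template_id,
                    "fwd_start": pred.fwd_start,
                    "rev_end": pred.rev_end,
                    "length": pred.length,
                    "fwd_mm": pred.fwd_mismatches,
                    "rev_mm": pred.rev_mismatches,
                }
            )
    summary = {
        "n_templates": n,
        "n_hits": len(lengths),
        "hit_rate": len(lengths) / n if n else float("nan"),
        "min_length": int(min(lengths)) if lengths else None,
        "median_length": float(np.median(lengths)) if lengths else None,
        "max_length": int(max(lengths)) if lengths else None,
    }
    return pd.DataFrame(rows), summary
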