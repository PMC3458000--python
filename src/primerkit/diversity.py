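"""Sliding-window nucleotide diversity (pi) over reference alignments.

Nucleotide diversity is Nei's pi: the mean, over all unordered sequence
pairs, of the per-site proportion of differences. Gaps are handled by
pairwise deletion — each pair is compared only at columns where both
sequences have an unambiguous base, and pairs with no comparable site in a
window are excluded from that window's mean. Scanning pi in fixed-length
windows advanced by a fixed step across an rRNA alignment exposes the
variable regions a metabarcoding amplicon should straddle, between the
conserved stretches where primers sit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compatibility import PrimerSite
from .reference import ReferenceAlignment

DEFAULT_WINDOW = 99
DEFAULT_STEP = 10


def _pair_stats(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per unordered pair (i<j): per-column comparable and differing flags.

    Returns (pair_index_i, comparable, differing); the latter two are
    (n_pairs, L) boolean arrays.
    """
    n = codes.shape[0]
    ii, jj = np.triu_indices(n, k=1)
    a = codes[ii]
    b = codes[jj]
    comparable = (a >= 0) & (b >= 0)
    differing = comparable & (a != b)
    return ii, comparable, differing


def pairwise_pi(window: ReferenceAlignment | np.ndarray) -> float:
    """Nucleotide diversity of an aligned slice.

    ``window`` is a :class:`ReferenceAlignment` or an (n, L) int code matrix
    (0..3 bases, -1 missing). Requires >= 2 sequences.
    """
    codes = window.codes() if isinstance(window, ReferenceAlignment) else np.asarray(window)
    if codes.shape[0] < 2:
        raise ValueError("pi requires at least 2 sequences")
    _, comparable, differing = _pair_stats(codes)
    comp = comparable.sum(axis=1)
    diff = differing.sum(axis=1)
    valid = comp > 0
    if not valid.any():
        return float("nan")
    return float((diff[valid] / comp[valid]).mean())


@dataclass
class DiversityTrack:
    """Windowed pi values across an alignment."""

    window_length: int
    step: int
    window_starts: np.ndarray  # 0-based start column of each window
    pi: np.ndarray

    def __len__(self) -> int:
        return len(self.window_starts)

    def to_frame(self) -> pd.DataFrame:
        """TSV-ready frame with 1-based inclusive window coordinates."""
        return pd.DataFrame(
            {
                "window_start": self.window_starts + 1,
                "window_end": self.window_starts + self.window_length,
                "pi": self.pi,
            }
        )


def sliding_window_pi(
    aln: ReferenceAlignment,
    window_length: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
) -> DiversityTrack:
    """Pi in windows of ``window_length`` columns advanced by ``step``.

    Produces floor((L - window_length)/step) + 1 windows starting at
    column 0. Cumulative per-pair sums make each window a constant-time
    difference rather than a fresh all-pairs scan.
    """
    if window_length < 1 or step < 1:
        raise ValueError("window_length and step must be >= 1")
    if aln.n_columns < window_length:
        raise ValueError(
            f"window length {window_length} exceeds alignment width {aln.n_columns}"
        )
    if len(aln) < 2:
        raise ValueError("pi requires at least 2 sequences")
    codes = aln.codes()
    _, comparable, differing = _pair_stats(codes)
    comp_cum = np.concatenate(
        [np.zeros((comparable.shape[0], 1), dtype=np.int64),
         comparable.cumsum(axis=1, dtype=np.int64)],
        axis=1,
    )
    diff_cum = np.concatenate(
        [np.zeros((differing.shape[0], 1), dtype=np.int64),
         differing.cumsum(axis=1, dtype=np.int64)],
        axis=1,
    )
    starts = np.arange(0, aln.n_columns - window_length + 1, step)
    pi = np.empty(starts.size, dtype=float)
    for w, s in enumerate(starts):
        comp = comp_cum[:, s + window_length] - comp_cum[:, s]
        diff = diff_cum[:, s + window_length] - diff_cum[:, s]
        valid = comp > 0
        pi[w] = (diff[valid] / comp[valid]).mean() if valid.any() else np.nan
    return DiversityTrack(window_length, step, starts, pi)


def filter_length_outliers(
    aln: ReferenceAlignment, max_deviation: float = 0.2
) -> tuple[ReferenceAlignment, pd.DataFrame]:
    """Optionally drop sequences whose unaligned length deviates from the
    median by more than ``max_deviation`` (fraction); mirrors manual removal
    of records with very large indels before diversity scans."""
    lengths = np.array([len(s.ungapped()) for s in aln])
    med = np.median(lengths) if len(aln) else 0
    keep, removed = [], []
    for i, seq in enumerate(aln):
        if med == 0 or abs(lengths[i] - med) <= max_deviation * med:
            keep.append(i)
        else:
            removed.append((seq.record_id, "length_outlier"))
    return aln.take(keep), pd.DataFrame(removed, columns=["record_id", "reason"])


def rank_amplicon_windows(
    track: DiversityTrack,
    site_pairs: list[tuple[PrimerSite, PrimerSite]],
    labels: list[str] | None = None,
) -> pd.DataFrame:
    """Rank primer-site pairs by the diversity of the region between them.

    For each (forward, reverse) site pair, summarizes pi over windows lying
    strictly between the sites (window start >= forward stop and window end
    <= reverse start) and ranks descending by mean pi, ties by max. Pairs
    with no fully interior window are flagged undefined and ranked last.
    """
    if labels is None:
        labels = [f"pair{i + 1}" for i in range(len(site_pairs))]
    rows = []
    for label, (fwd, rev) in zip(labels, site_pairs):
        if fwd.stop > rev.start:
            raise ValueError(
                f"{label}: forward site must precede the reverse site"
            )
        inside = (track.window_starts >= fwd.stop) & (
            track.window_starts + track.window_length <= rev.start
        )
        vals = track.pi[inside]
        vals = vals[~np.isnan(vals)]
        if vals.size:
            rows.append(
                {
                    "pair": label,
                    "n_windows": int(vals.size),
                    "mean_pi": float(vals.mean()),
                    "max_pi": float(vals.max()),
                    "defined": True,
                }
            )
        else:
            rows.append(
                {
                    "pair": label,
                    "n_windows": 0,
                    "mean_pi": np.nan,
                    "max_pi": np.nan,
                    "defined": False,
                }
            )
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["defined", "mean_pi", "max_pi"],
        ascending=[False, False, False],
        na_position="last",
        kind="mergesort",
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
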