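"""Genomic interval primitives.

All coordinates follow the BED convention: 0-based, half-open ``[start, end)``.
Chromosome names are compared by exact string match (no ``chr`` aliasing).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "Interval",
    "overlap_length",
    "intersect_sets",
    "merge_intervals",
    "intervals_to_frame",
    "frame_to_intervals",
    "count_overlaps",
]

_VALID_STRANDS = {"+", "-", "."}


@dataclass(slots=True)
class Interval:
    """A genomic span ``[start, end)`` on a chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome name (nonempty, exact-match semantics).
    start, end : int
        0-based half-open coordinates with ``0 <= start < end``.
    name, score, strand : optional
        BED-style annotation fields.
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand is not None and self.strand not in _VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def overlap_length(a: Interval, b: Interval) -> int:
    """Overlap in bp between two intervals; 0 on different chromosomes."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def _trees_by_chrom(intervals: Sequence[Interval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for i, iv in enumerate(intervals):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, i)
    return trees


def intersect_sets(
    set_a: Sequence[Interval],
    set_b: Sequence[Interval],
    min_bp: int = 1,
) -> list[tuple[int, int]]:
    """All index pairs ``(i, j)`` with ``overlap_length(a[i], b[j]) >= min_bp``.

    Pairs are returned sorted by ``(i, j)``.
    """
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    trees = _trees_by_chrom(set_b)
    pairs: list[tuple[int, int]] = []
    for i, a in enumerate(set_a):
        tree = trees.get(a.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(a.start, a.end):
            if min(a.end, hit.end) - max(a.start, hit.begin) >= min_bp:
                pairs.append((i, hit.data))
    pairs.sort()
    return pairs


def merge_intervals(intervals: Iterable[Interval], gap: int = 0) -> list[Interval]:
    """Union of intervals per chromosome, bridging gaps ``<= gap`` bp.

    With ``gap=0`` touching intervals (``a.end == b.start``) are joined,
    matching ``bedtools merge`` semantics.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    by_chrom: dict[str, list[Interval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[Interval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda x: (x.start, x.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end + gap:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(Interval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(Interval(chrom, cur_start, cur_end))
    return merged


def intervals_to_frame(intervals: Sequence[Interval]) -> pd.DataFrame:
    """Convert a list of :class:`Interval` to a chrom/start/end DataFrame."""
    return pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in intervals],
            "start": np.asarray([iv.start for iv in intervals], dtype=np.int64),
            "end": np.asarray([iv.end for iv in intervals], dtype=np.int64),
        }
    )


def frame_to_intervals(frame: pd.DataFrame) -> list[Interval]:
    """Inverse of :func:`intervals_to_frame` (chrom/start/end columns only)."""
    return [
        Interval(c, int(s), int(e))
        for c, s, e in zip(frame["chrom"], frame["start"], frame["end"])
    ]


def _as_frame(intervals) -> pd.DataFrame:
    if isinstance(intervals, pd.DataFrame):
        return intervals
    return intervals_to_frame(list(intervals))


def count_overlaps(
    fragments,
    windows: Sequence[Interval],
    min_overlap: int = 1,
) -> np.ndarray:
    """Number of fragments overlapping each window by ``>= min_overlap`` bp.

    ``fragments`` may be a sequence of :class:`Interval` or a DataFrame with
    ``chrom``/``start``/``end`` columns (the scalable representation for
    simulated libraries). Uses the counting identity

        count(w) = #{f : f.start <= w.end - m} - #{f : f.end < w.start + m}

    per chromosome on fragments of length ``>= m``, valid whenever the window
    is at least ``m`` bp wide (the second set is then a subset of the first).
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    frame = _as_frame(fragments)
    counts = np.zeros(len(windows), dtype=np.int64)
    if frame.empty or not windows:
        return counts
    lengths = frame["end"].to_numpy() - frame["start"].to_numpy()
    keep = lengths >= min_overlap
    sub = frame.loc[keep]
    for chrom, grp in sub.groupby("chrom", sort=False):
        idx = [i for i, w in enumerate(windows) if w.chrom == chrom]
        if not idx:
            continue
        starts = np.sort(grp["start"].to_numpy())
        ends = np.sort(grp["end"].to_numpy())
        w_start = np.array([windows[i].start for i in idx], dtype=np.int64)
        w_end = np.array([windows[i].end for i in idx], dtype=np.int64)
        ok = (w_end - w_start) >= min_overlap
        n_le = np.searchsorted(starts, w_end - min_overlap, side="right")
        n_lt = np.searchsorted(ends, w_start + min_overlap, side="left")
        c = np.where(ok, n_le - n_lt, 0)
        counts[np.asarray(idx)] += c
    return counts
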