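"""Genomic interval algebra.

All coordinates follow the BED convention: 0-based, half-open
``[start, end)``. Interval sets are plain containers over sorted numpy
arrays; the algebra (merge, subtract, window overlap) is implemented
directly so that every operation can be checked against per-base boolean
oracles in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "merge_intervals",
    "subtract_intervals",
    "window_overlap",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self!r}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: {self!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class IntervalSet:
    """An ordered collection of intervals with optional labels and scores.

    Parameters
    ----------
    intervals
        The member intervals; stored in the order given.
    labels
        Optional per-interval string labels (e.g. chromatin state,
        provenance tags).
    scores
        Optional per-interval float scores (e.g. peak signal).
    """

    intervals: list[GenomicInterval] = field(default_factory=list)
    labels: list[str] | None = None
    scores: list[float] | None = None

    def __post_init__(self) -> None:
        self.intervals = list(self.intervals)
        if self.labels is not None:
            self.labels = list(self.labels)
            if len(self.labels) != len(self.intervals):
                raise ValueError("labels length mismatch")
        if self.scores is not None:
            self.scores = [float(s) for s in self.scores]
            if len(self.scores) != len(self.intervals):
                raise ValueError("scores length mismatch")

    @classmethod
    def from_tuples(
        cls,
        tuples: Iterable[tuple],
        labels: Sequence[str] | None = None,
        scores: Sequence[float] | None = None,
    ) -> "IntervalSet":
        ivs = [GenomicInterval(str(c), int(s), int(e)) for c, s, e in tuples]
        return cls(ivs, list(labels) if labels is not None else None,
                   list(scores) if scores is not None else None)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def total_bases(self) -> int:
        """Sum of interval lengths (double-counts overlapping bases)."""
        return sum(len(iv) for iv in self.intervals)

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for iv in self.intervals:
            seen.setdefault(iv.chrom, None)
        return sorted(seen)

    def sorted(self) -> "IntervalSet":
        order = sorted(
            range(len(self.intervals)),
            key=lambda i: (self.intervals[i].chrom,
                           self.intervals[i].start,
                           self.intervals[i].end),
        )
        return self._take(order)

    def _take(self, order: Sequence[int]) -> "IntervalSet":
        return IntervalSet(
            [self.intervals[i] for i in order],
            [self.labels[i] for i in order] if self.labels is not None else None,
            [self.scores[i] for i in order] if self.scores is not None else None,
        )

    def by_chrom(self) -> dict[str, np.ndarray]:
        """Per-chromosome ``(n, 2)`` start/end arrays, each sorted by start."""
        out: dict[str, list[tuple[int, int]]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append((iv.start, iv.end))
        return {
            c: np.array(sorted(v), dtype=np.int64).reshape(-1, 2)
            for c, v in out.items()
        }

    def is_merged(self) -> bool:
        for arr in self.by_chrom().values():
            if np.any(arr[1:, 0] < arr[:-1, 1]):
                return False
        return True


def merge_intervals(intervals: IntervalSet, label_sep: str = ",") -> IntervalSet:
    """Merge overlapping (book-ended are also joined) intervals per chromosome.

    Labels of merged constituents are concatenated with ``label_sep`` onto
    each output interval, in input sort order.
    """
    if len(intervals) == 0:
        return IntervalSet()
    srt = intervals.sorted()
    has_labels = srt.labels is not None
    out_ivs: list[GenomicInterval] = []
    out_labels: list[str] = []
    cur: GenomicInterval | None = None
    cur_labels: list[str] = []
    for i, iv in enumerate(srt.intervals):
        if cur is not None and iv.chrom == cur.chrom and iv.start <= cur.end:
            cur = GenomicInterval(cur.chrom, cur.start, max(cur.end, iv.end))
            if has_labels:
                cur_labels.append(srt.labels[i])  # type: ignore[index]
        else:
            if cur is not None:
                out_ivs.append(cur)
                out_labels.append(label_sep.join(cur_labels))
            cur = iv
            cur_labels = [srt.labels[i]] if has_labels else []  # type: ignore[index]
    out_ivs.append(cur)  # type: ignore[arg-type]
    out_labels.append(label_sep.join(cur_labels))
    return IntervalSet(out_ivs, out_labels if has_labels else None)


def subtract_intervals(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Bases of ``a`` not covered by ``b``; intervals split where needed.

    Labels/scores of ``a`` propagate to every surviving fragment.
    """
    b_by_chrom = merge_intervals(b).by_chrom() if len(b) else {}
    out_ivs: list[GenomicInterval] = []
    out_labels: list[str] = []
    out_scores: list[float] = []
    has_labels = a.labels is not None
    has_scores = a.scores is not None
    for i, iv in enumerate(a.intervals):
        blocks = b_by_chrom.get(iv.chrom)
        pieces: list[tuple[int, int]] = []
        pos = iv.start
        if blocks is not None:
            # blocks are merged & sorted; walk the ones overlapping iv
            lo = int(np.searchsorted(blocks[:, 1], iv.start, side="right"))
            for bs, be in blocks[lo:]:
                if bs >= iv.end:
                    break
                if bs > pos:
                    pieces.append((pos, bs))
                pos = max(pos, be)
        if pos < iv.end:
            pieces.append((pos, iv.end))
        for s, e in pieces:
            out_ivs.append(GenomicInterval(iv.chrom, s, e))
            if has_labels:
                out_labels.append(a.labels[i])  # type: ignore[index]
            if has_scores:
                out_scores.append(a.scores[i])  # type: ignore[index]
    return IntervalSet(
        out_ivs,
        out_labels if has_labels else None,
        out_scores if has_scores else None,
    )


def window_overlap(
    regions: IntervalSet,
    anchors: Iterable[tuple[str, int]],
    flank: int,
) -> np.ndarray:
    """Flag regions intersecting ``[anchor - flank, anchor + flank)``.

    Parameters
    ----------
    regions
        Query regions.
    anchors
        ``(chrom, position)`` anchor points (e.g. TSSs).
    flank
        Half-width of the symmetric window, in bp; must be positive.

    Returns
    -------
    numpy.ndarray
        Boolean vector, one flag per region, true iff the region
        intersects the window of at least one anchor.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    windows: dict[str, list[tuple[int, int]]] = {}
    region_chroms = {iv.chrom for iv in regions}
    for chrom, pos in anchors:
        chrom = str(chrom)
        if chrom not in region_chroms:
            logger.warning("anchor chromosome %s absent from regions", chrom)
        windows.setdefault(chrom, []).append((max(0, int(pos) - flank), int(pos) + flank))
    win_arr = {c: np.array(sorted(v), dtype=np.int64) for c, v in windows.items()}
    flags = np.zeros(len(regions), dtype=bool)
    for i, iv in enumerate(regions.intervals):
        arr = win_arr.get(iv.chrom)
        if arr is None:
            continue
        # overlap iff window.start < iv.end and window.end > iv.start
        j = int(np.searchsorted(arr[:, 0], iv.end, side="left"))
        flags[i] = bool(np.any(arr[:j, 1] > iv.start))
    return flags
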