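"""Core genomic-interval primitives.

Coordinates are 0-based, half-open throughout the package; GTF/GFF3 input is
converted on read, BED passes through unchanged.  These types are the common
currency between every analysis stage, so they stay deliberately small:
a frozen interval record, a chromosome layout, and a handful of set
operations (merge, complement, sweep-line intersection) plus two vectorized
indexes used for fragment counting and overlap queries.
"""

from __future__ import annotations

import heapq
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A half-open genomic span ``[start, end)`` with an optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class GenomeLayout:
    """Ordered chromosome names and lengths; the coordinate space for
    windowing and shuffling."""

    chrom_lengths: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.chrom_lengths:
            raise ValueError("layout needs at least one chromosome")
        self.chrom_lengths = dict(self.chrom_lengths)
        for name, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(self.chrom_lengths)

    @property
    def lengths(self) -> np.ndarray:
        return np.asarray(list(self.chrom_lengths.values()), dtype=np.int64)

    @property
    def total_length(self) -> int:
        return int(self.lengths.sum())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_lengths

    def length_of(self, chrom: str) -> int:
        return self.chrom_lengths[chrom]

    def contains(self, interval: GenomicInterval) -> bool:
        return (
            interval.chrom in self.chrom_lengths
            and interval.end <= self.chrom_lengths[interval.chrom]
        )

    def clip(self, chrom: str, start: int, end: int, strand: str = ".") -> GenomicInterval | None:
        """Clip ``[start, end)`` to the chromosome; None if nothing remains."""
        limit = self.chrom_lengths[chrom]
        start, end = max(0, start), min(limit, end)
        if end <= start:
            return None
        return GenomicInterval(chrom, start, end, strand)


def sort_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    return sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))


def total_bp(intervals: Iterable[GenomicInterval]) -> int:
    return sum(iv.length for iv in intervals)


def group_by_chrom(
    intervals: Sequence[GenomicInterval],
) -> dict[str, list[tuple[int, GenomicInterval]]]:
    """Original indices grouped per chromosome (insertion order preserved)."""
    out: dict[str, list[tuple[int, GenomicInterval]]] = {}
    for i, iv in enumerate(intervals):
        out.setdefault(iv.chrom, []).append((i, iv))
    return out


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals: sorted, strand-agnostic, overlaps and bookends merged."""
    merged: list[GenomicInterval] = []
    for iv in sort_intervals(intervals):
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            if iv.end > merged[-1].end:
                merged[-1] = GenomicInterval(iv.chrom, merged[-1].start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def complement_intervals(
    intervals: Iterable[GenomicInterval], layout: GenomeLayout
) -> list[GenomicInterval]:
    """Per-chromosome complement of the merged input within the layout."""
    merged = merge_intervals(intervals)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in merged:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for chrom, limit in layout.chrom_lengths.items():
        cursor = 0
        for iv in by_chrom.get(chrom, []):
            if iv.start > cursor:
                out.append(GenomicInterval(chrom, cursor, min(iv.start, limit)))
            cursor = max(cursor, iv.end)
        if cursor < limit:
            out.append(GenomicInterval(chrom, cursor, limit))
    return out


class Overlap(NamedTuple):
    index_a: int
    index_b: int
    bp: int


def intersect_intervals(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[Overlap]:
    """All pairs ``(i, j)`` with >= 1 bp overlap between ``a[i]`` and ``b[j]``.

    Sweep-line: both sides are processed in start order per chromosome; an
    active heap keyed by end position holds the b-intervals that can still
    overlap future a-intervals.  O((n + m) log m + k) for k reported pairs.
    """
    by_chrom_a = group_by_chrom(a)
    by_chrom_b = group_by_chrom(b)
    hits: list[Overlap] = []
    for chrom, a_items in by_chrom_a.items():
        b_items = by_chrom_b.get(chrom)
        if not b_items:
            continue
        a_sorted = sorted(a_items, key=lambda t: t[1].start)
        b_sorted = sorted(b_items, key=lambda t: t[1].start)
        active: list[tuple[int, int, int]] = []  # (end, orig_index, start)
        j = 0
        for ia, iva in a_sorted:
            while j < len(b_sorted) and b_sorted[j][1].start < iva.end:
                ib, ivb = b_sorted[j]
                heapq.heappush(active, (ivb.end, ib, ivb.start))
                j += 1
            while active and active[0][0] <= iva.start:
                heapq.heappop(active)
            for end, ib, start in active:
                bp = min(iva.end, end) - max(iva.start, start)
                if bp > 0:
                    hits.append(Overlap(ia, ib, bp))
    hits.sort()
    return hits


class ChromIndex:
    """Independently sorted start/end arrays per chromosome.

    Supports vectorized counting of how many intervals overlap each query
    window: an interval misses ``[s, e)`` iff it ends at or before ``s`` or
    starts at or after ``e``, and those two miss-sets are disjoint.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] | Mapping[str, tuple[np.ndarray, np.ndarray]]):
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        if isinstance(intervals, Mapping):
            items = intervals.items()
            for chrom, (starts, ends) in items:
                self._starts[chrom] = np.sort(np.asarray(starts, dtype=np.int64))
                self._ends[chrom] = np.sort(np.asarray(ends, dtype=np.int64))
        else:
            raw: dict[str, list[tuple[int, int]]] = {}
            for iv in intervals:
                raw.setdefault(iv.chrom, []).append((iv.start, iv.end))
            for chrom, pairs in raw.items():
                arr = np.asarray(pairs, dtype=np.int64)
                self._starts[chrom] = np.sort(arr[:, 0])
                self._ends[chrom] = np.sort(arr[:, 1])
        self.total = int(sum(len(v) for v in self._starts.values()))

    def count_overlapping(
        self, chrom: str, starts: np.ndarray, ends: np.ndarray
    ) -> np.ndarray:
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if chrom not in self._starts:
            return np.zeros(starts.shape, dtype=np.int64)
        s_sorted = self._starts[chrom]
        e_sorted = self._ends[chrom]
        n = len(s_sorted)
        ended_before = np.searchsorted(e_sorted, starts, side="right")
        start_after = n - np.searchsorted(s_sorted, ends, side="left")
        return n - ended_before - start_after


class MergedIndex:
    """Merged, sorted interval set answering any-overlap queries in O(log n)."""

    def __init__(self, intervals: Iterable[GenomicInterval]):
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        merged = merge_intervals(intervals)
        raw: dict[str, list[tuple[int, int]]] = {}
        for iv in merged:
            raw.setdefault(iv.chrom, []).append((iv.start, iv.end))
        for chrom, pairs in raw.items():
            arr = np.asarray(pairs, dtype=np.int64)
            self._starts[chrom] = arr[:, 0]
            self._ends[chrom] = arr[:, 1]

    def overlaps_any(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if chrom not in self._starts:
            return np.zeros(starts.shape, dtype=bool)
        f_starts = self._starts[chrom]
        f_ends = self._ends[chrom]
        idx = np.searchsorted(f_ends, starts, side="right")
        hit = idx < len(f_starts)
        safe = np.where(hit, idx, 0)
        return hit & (f_starts[safe] < ends)

    def coverage_bp(self) -> int:
        return int(
            sum((e - s).sum() for s, e in zip(self._starts.values(), self._ends.values()))
        )
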