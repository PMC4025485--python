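"""Methylation ratio scoring over windows, peak canonicalization.

The quantitative methylation measure is the ratio of normalized fragment
densities from the methylation-enriched capture versus the unenriched
flow-through of the same library:

    ratio(w) = (e_w / E) / (u_w / U)

where ``e_w``/``u_w`` count fragments overlapping window ``w`` by >= 1 bp and
``E``/``U`` are the library totals.  A fragment is counted by interval
overlap (not 5' end or midpoint) because ~300 bp sonication fragments exceed
fine windows.  When the flow-through count is zero but the enriched count is
not, the denominator count is replaced by a half-count of 0.5 to keep the
ratio finite; windows with no enriched fragments score 0.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .intervals import ChromIndex, GenomeLayout, GenomicInterval, group_by_chrom

logger = logging.getLogger(__name__)


class FragmentSet:
    """Fragment placements of one library plus its library-wide total.

    ``total_count`` is the normalization constant E (or U); it defaults to
    the number of fragments supplied but may be larger when only a subset of
    a library is loaded.
    """

    def __init__(
        self,
        label: str,
        fragments: Sequence[GenomicInterval] | Mapping[str, tuple[np.ndarray, np.ndarray]],
        total_count: int | None = None,
    ):
        if label not in ("enriched", "unenriched"):
            raise ValueError("library_label must be 'enriched' or 'unenriched'")
        self.label = label
        if isinstance(fragments, Mapping):
            self._arrays = {
                chrom: (
                    np.asarray(starts, dtype=np.int64),
                    np.asarray(ends, dtype=np.int64),
                )
                for chrom, (starts, ends) in fragments.items()
            }
        else:
            raw: dict[str, list[tuple[int, int]]] = {}
            for iv in fragments:
                raw.setdefault(iv.chrom, []).append((iv.start, iv.end))
            self._arrays = {}
            for chrom, pairs in raw.items():
                arr = np.asarray(pairs, dtype=np.int64)
                self._arrays[chrom] = (arr[:, 0], arr[:, 1])
        self.n_fragments = int(sum(len(s) for s, _ in self._arrays.values()))
        self.total_count = int(total_count) if total_count is not None else self.n_fragments
        if self.total_count < self.n_fragments:
            raise ValueError("total_count must be >= number of fragments supplied")
        self._index = ChromIndex(self._arrays)

    @classmethod
    def from_bed(
        cls, path: str | Path, label: str, total_count: int | None = None
    ) -> "FragmentSet":
        return cls(label, mio.read_bed(path), total_count)

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self._arrays):
                starts, ends = self._arrays[chrom]
                order = np.lexsort((ends, starts))
                for s, e in zip(starts[order], ends[order]):
                    fh.write(f"{chrom}\t{s}\t{e}\n")

    def count_overlapping(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        return self._index.count_overlapping(chrom, starts, ends)

    def intervals(self) -> list[GenomicInterval]:
        out = []
        for chrom in sorted(self._arrays):
            starts, ends = self._arrays[chrom]
            out.extend(
                GenomicInterval(chrom, int(s), int(e)) for s, e in zip(starts, ends)
            )
        return out


@dataclass
class PeakSet:
    """Called peaks; ``expanded`` marks the canonical center +/- 100 bp form."""

    peaks: list[GenomicInterval]
    scores: list[float] | None = None
    expanded: bool = False

    def __len__(self) -> int:
        return len(self.peaks)

    @classmethod
    def from_bed(cls, path: str | Path, expanded: bool = False) -> "PeakSet":
        return cls(mio.read_bed(path), expanded=expanded)

    def to_bed(self, path: str | Path) -> None:
        mio.write_bed(self.peaks, path, scores=self.scores)


def expand_peaks(peaks: PeakSet, layout: GenomeLayout, flank: int = 100) -> PeakSet:
    """Replace each peak by its center +/- ``flank`` bp, clipped to the
    chromosome; the center of even-length peaks is the floor midpoint."""
    if peaks.expanded:
        raise ValueError("peak set is already expanded")
    out = []
    for iv in peaks.peaks:
        center = (iv.start + iv.end) // 2
        clipped = layout.clip(iv.chrom, center - flank, center + flank, iv.strand)
        if clipped is None:  # zero-length after clipping cannot happen for flank > 0
            continue
        out.append(clipped)
    return PeakSet(out, scores=peaks.scores, expanded=True)


def partition_windows(
    interval: GenomicInterval, n_windows: int = 20
) -> list[GenomicInterval]:
    """Tile ``interval`` with ``n_windows`` contiguous windows in 5'->3' order.

    Window widths differ by at most 1 bp; the remainder is spread from the 5'
    end.  On the minus strand window index 0 is the 5'-most (genomic
    rightmost) window.  Raises ValueError when the interval is shorter than
    ``n_windows``.
    """
    length = interval.length
    if length < n_windows:
        raise ValueError(
            f"interval of {length} bp cannot form {n_windows} windows"
        )
    base, rem = divmod(length, n_windows)
    widths = [base + 1] * rem + [base] * (n_windows - rem)  # 5'->3'
    windows = []
    if interval.strand == "-":
        edge = interval.end
        for w in widths:
            windows.append(
                GenomicInterval(interval.chrom, edge - w, edge, interval.strand)
            )
            edge -= w
    else:
        edge = interval.start
        for w in widths:
            windows.append(
                GenomicInterval(interval.chrom, edge, edge + w, interval.strand)
            )
            edge += w
    return windows


@dataclass
class MethylationRatioTrack:
    """Per-window enriched/unenriched normalized density ratio."""

    windows: list[GenomicInterval]
    ratio: np.ndarray
    enriched_count: np.ndarray
    unenriched_count: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [w.chrom for w in self.windows],
                "start": [w.start for w in self.windows],
                "end": [w.end for w in self.windows],
                "strand": [w.strand for w in self.windows],
                "ratio": self.ratio,
                "enriched_count": self.enriched_count,
                "unenriched_count": self.unenriched_count,
            }
        )

    def to_bedgraph(self, path: str | Path) -> None:
        mio.write_bedgraph(self.windows, self.ratio, path)


def count_in_windows(
    windows: Sequence[GenomicInterval], fragments: FragmentSet
) -> np.ndarray:
    """Fragments overlapping each window by >= 1 bp (vectorized per chrom)."""
    counts = np.zeros(len(windows), dtype=np.int64)
    for chrom, items in group_by_chrom(windows).items():
        idx = np.asarray([i for i, _ in items], dtype=np.int64)
        starts = np.asarray([iv.start for _, iv in items], dtype=np.int64)
        ends = np.asarray([iv.end for _, iv in items], dtype=np.int64)
        counts[idx] = fragments.count_overlapping(chrom, starts, ends)
    return counts


def ratio_from_counts(
    e: np.ndarray,
    u: np.ndarray,
    total_enriched: int,
    total_unenriched: int,
    zero_unenriched: float = 0.5,
) -> np.ndarray:
    if total_enriched <= 0 or total_unenriched <= 0:
        raise ValueError("library totals must be positive")
    e = np.asarray(e, dtype=float)
    u = np.asarray(u, dtype=float)
    u_safe = np.where((u == 0) & (e > 0), zero_unenriched, u)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (e / total_enriched) / (u_safe / total_unenriched)
    return np.where(e == 0, 0.0, ratio)


def methylation_ratio(
    windows: Sequence[GenomicInterval],
    enriched: FragmentSet,
    unenriched: FragmentSet,
    zero_unenriched: float = 0.5,
) -> MethylationRatioTrack:
    """Methylation ratio score per window (see module docstring)."""
    e = count_in_windows(windows, enriched)
    u = count_in_windows(windows, unenriched)
    ratio = ratio_from_counts(
        e, u, enriched.total_count, unenriched.total_count, zero_unenriched
    )
    return MethylationRatioTrack(list(windows), ratio, e, u)


def fixed_windows(layout: GenomeLayout, size: int = 200) -> list[GenomicInterval]:
    """Genome-wide non-overlapping tiling; the terminal partial window is kept."""
    if size <= 0:
        raise ValueError("window size must be positive")
    windows = []
    for chrom, length in layout.chrom_lengths.items():
        starts = range(0, length, size)
        windows.extend(
            GenomicInterval(chrom, s, min(s + size, length)) for s in starts
        )
    return windows


def fragment_counts_fixed_windows(
    fragments: FragmentSet, layout: GenomeLayout, size: int = 200
) -> dict[str, np.ndarray]:
    """Per-chromosome arrays of fragment counts on the fixed window grid."""
    out = {}
    for chrom, length in layout.chrom_lengths.items():
        starts = np.arange(0, length, size, dtype=np.int64)
        ends = np.minimum(starts + size, length)
        out[chrom] = fragments.count_overlapping(chrom, starts, ends)
    return out
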