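"""Shuffle-bootstrap interval enrichment.

The observed statistic is the number of peaks overlapping a feature track by
>= 1 bp.  The null distribution re-places every peak uniformly at random
(chromosome chosen with probability proportional to its length among
chromosomes long enough, length preserved) ``n_shuffles`` times; enrichment
is observed / null mean, with the null SD reported both on the count scale
and rescaled to the enrichment ratio.  Empirical p-values use the standard
add-one rule, so the floor at B shuffles is 1/(B+1).
"""

from __future__ import annotations

import logging
import math
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import (
    GenomeLayout,
    GenomicInterval,
    MergedIndex,
    group_by_chrom,
    intersect_intervals,
)
from .scoring import PeakSet

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    feature_name: str
    observed: int
    null_mean: float
    null_sd: float  # SD of the null counts
    enrichment: float
    enrichment_sd: float  # null_sd rescaled to the enrichment ratio
    empirical_p: float  # one-sided, in the direction of the effect
    p_greater: float
    p_less: float
    p_two_sided: float
    n_shuffles: int
    se: float  # Monte-Carlo SE of the enrichment ratio

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class PeakComparison:
    """Classification of two peak sets into shared and set-unique peaks."""

    pairs: list[tuple[int, int]]  # (index in a, index in b) overlapping pairs
    shared_a: list[GenomicInterval]
    unique_a: list[GenomicInterval]
    shared_b: list[GenomicInterval]
    unique_b: list[GenomicInterval]

    @property
    def n_shared_a(self) -> int:
        return len(self.shared_a)

    @property
    def n_shared_b(self) -> int:
        return len(self.shared_b)


def _peak_list(peaks: PeakSet | Sequence[GenomicInterval]) -> list[GenomicInterval]:
    return list(peaks.peaks) if isinstance(peaks, PeakSet) else list(peaks)


def shuffle_intervals(
    intervals: Sequence[GenomicInterval],
    layout: GenomeLayout,
    rng: np.random.Generator | int,
    exclude: MergedIndex | None = None,
    max_tries: int = 100,
) -> list[GenomicInterval]:
    """Re-place each interval uniformly at random, preserving its length.

    With an ``exclude`` index, placements overlapping the excluded track are
    re-drawn (rejection sampling, up to ``max_tries`` rounds).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    chroms = list(layout.chrom_names)
    lens = layout.lengths
    lengths = np.asarray([iv.length for iv in intervals], dtype=np.int64)
    n = len(lengths)
    if n == 0:
        return []
    if lengths.max() > lens.max():
        raise ValueError("an interval is longer than every chromosome")
    chrom_idx = np.empty(n, dtype=np.int64)
    if lengths.max() <= lens.min():
        p = lens / lens.sum()
        chrom_idx[:] = rng.choice(len(chroms), size=n, p=p)
    else:
        for i, length in enumerate(lengths):
            ok = np.flatnonzero(lens >= length)
            p = lens[ok] / lens[ok].sum()
            chrom_idx[i] = ok[rng.choice(len(ok), p=p)]
    high = lens[chrom_idx] - lengths + 1  # start uniform on [0, chrom_len - L]
    starts = np.floor(rng.random(n) * high).astype(np.int64)
    if exclude is not None:
        for _ in range(max_tries):
            bad = np.zeros(n, dtype=bool)
            for ci in np.unique(chrom_idx):
                mask = chrom_idx == ci
                bad[mask] = exclude.overlaps_any(
                    chroms[ci], starts[mask], starts[mask] + lengths[mask]
                )
            if not bad.any():
                break
            starts[bad] = np.floor(
                rng.random(int(bad.sum())) * high[bad]
            ).astype(np.int64)
        else:
            raise RuntimeError("could not place intervals outside exclusion track")
    return [
        GenomicInterval(chroms[ci], int(s), int(s + length))
        for ci, s, length in zip(chrom_idx, starts, lengths)
    ]


def _count_overlapping_peaks(
    index: MergedIndex, chrom_idx: np.ndarray, starts: np.ndarray,
    lengths: np.ndarray, chroms: list[str],
) -> int:
    total = 0
    for ci in np.unique(chrom_idx):
        mask = chrom_idx == ci
        total += int(
            index.overlaps_any(
                chroms[ci], starts[mask], starts[mask] + lengths[mask]
            ).sum()
        )
    return total


def count_peaks_in_feature(
    peaks: PeakSet | Sequence[GenomicInterval],
    feature: Sequence[GenomicInterval] | MergedIndex,
) -> int:
    """Number of peaks overlapping >= 1 feature interval."""
    index = feature if isinstance(feature, MergedIndex) else MergedIndex(feature)
    total = 0
    for chrom, items in group_by_chrom(_peak_list(peaks)).items():
        starts = np.asarray([iv.start for _, iv in items], dtype=np.int64)
        ends = np.asarray([iv.end for _, iv in items], dtype=np.int64)
        total += int(index.overlaps_any(chrom, starts, ends).sum())
    return total


def bootstrap_enrichment(
    peaks: PeakSet | Sequence[GenomicInterval],
    feature: Sequence[GenomicInterval],
    layout: GenomeLayout,
    n_shuffles: int = 1000,
    seed: int | None = 0,
    feature_name: str = "feature",
    exclude: Sequence[GenomicInterval] | None = None,
) -> EnrichmentResult:
    """Observed vs shuffled peak/feature intersection counts.

    Each shuffle uses an independent RNG stream spawned deterministically
    from ``seed``, so results do not depend on evaluation order.
    """
    peak_list = _peak_list(peaks)
    if not feature:
        raise ValueError("feature track is empty")
    index = MergedIndex(feature)
    exclude_index = MergedIndex(exclude) if exclude else None
    observed = count_peaks_in_feature(peak_list, index)

    chroms = list(layout.chrom_names)
    lens = layout.lengths
    lengths = np.asarray([iv.length for iv in peak_list], dtype=np.int64)
    if len(lengths) and lengths.max() > lens.max():
        raise ValueError("a peak is longer than every chromosome")
    simple = len(lengths) > 0 and lengths.max() <= lens.min() and exclude_index is None
    p_chrom = lens / lens.sum()

    null = np.empty(n_shuffles, dtype=np.int64)
    children = np.random.SeedSequence(seed).spawn(n_shuffles)
    for b, child in enumerate(children):
        rng = np.random.default_rng(child)
        if simple:
            chrom_idx = rng.choice(len(chroms), size=len(lengths), p=p_chrom)
            starts = np.floor(
                rng.random(len(lengths)) * (lens[chrom_idx] - lengths + 1)
            ).astype(np.int64)
            null[b] = _count_overlapping_peaks(index, chrom_idx, starts, lengths, chroms)
        else:
            shuffled = shuffle_intervals(peak_list, layout, rng, exclude_index)
            null[b] = count_peaks_in_feature(shuffled, index)

    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1)) if n_shuffles > 1 else 0.0
    if null_mean > 0:
        enrichment = observed / null_mean
        enrichment_sd = null_sd / null_mean
        se = enrichment * null_sd / (null_mean * math.sqrt(n_shuffles))
    else:
        enrichment = math.inf if observed > 0 else 1.0
        enrichment_sd = math.nan
        se = math.nan
        logger.warning("null mean is zero for %s; enrichment is infinite", feature_name)
    p_greater = (1 + int((null >= observed).sum())) / (1 + n_shuffles)
    p_less = (1 + int((null <= observed).sum())) / (1 + n_shuffles)
    p_two = min(1.0, 2 * min(p_greater, p_less))
    return EnrichmentResult(
        feature_name=feature_name,
        observed=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        enrichment=enrichment,
        enrichment_sd=enrichment_sd,
        empirical_p=p_greater if enrichment >= 1 else p_less,
        p_greater=p_greater,
        p_less=p_less,
        p_two_sided=p_two,
        n_shuffles=n_shuffles,
        se=se,
    )


def enrichment_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])


def compare_peak_sets(a: PeakSet, b: PeakSet) -> PeakComparison:
    """Classify peaks of each set as shared (>= 1 bp overlap with any peak of
    the other set) or unique; classification is independent per set."""
    if not (a.expanded and b.expanded):
        raise ValueError("both peak sets must be expanded before comparison")
    pairs = [(h.index_a, h.index_b) for h in intersect_intervals(a.peaks, b.peaks)]
    shared_ia = {ia for ia, _ in pairs}
    shared_ib = {ib for _, ib in pairs}
    return PeakComparison(
        pairs=pairs,
        shared_a=[iv for i, iv in enumerate(a.peaks) if i in shared_ia],
        unique_a=[iv for i, iv in enumerate(a.peaks) if i not in shared_ia],
        shared_b=[iv for i, iv in enumerate(b.peaks) if i in shared_ib],
        unique_b=[iv for i, iv in enumerate(b.peaks) if i not in shared_ib],
    )
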