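"""Genome-averaged meta-gene methylation profiles.

Every meta-gene element is resolved into 20 strand-oriented windows (5% of
the element length each), the methylation ratio is scored per window, and
windows are averaged per element class across the genome with equal weight
per element so long genes do not dominate.  Also provides the intron/exon
boundary profile around 3' intron ends and expression-decile stratified
profiles.
"""

from __future__ import annotations

import logging
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import ELEMENT_CLASSES, GeneModel, MetaGeneElement
from .scoring import (
    FragmentSet,
    count_in_windows,
    methylation_ratio,
    partition_windows,
    ratio_from_counts,
)

logger = logging.getLogger(__name__)


@dataclass
class MetaGeneProfile:
    """Mean ratio per window index (20 per class) with contributing counts."""

    data: dict[str, np.ndarray]  # element_class -> (n_windows,) means
    n_elements: dict[str, int]
    tissue: str = ""
    n_windows: int = 20

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for cls in ELEMENT_CLASSES:
            if cls not in self.data:
                continue
            for w, value in enumerate(self.data[cls]):
                rows.append(
                    {
                        "element_class": cls,
                        "window_index": w,
                        "mean_ratio": value,
                        "n": self.n_elements[cls],
                    }
                )
        return pd.DataFrame(rows)

    def class_mean(self, cls: str) -> float:
        return float(np.mean(self.data[cls]))


def metagene_profile(
    elements: Sequence[MetaGeneElement],
    enriched: FragmentSet,
    unenriched: FragmentSet,
    n_windows: int = 20,
    tissue: str = "",
) -> MetaGeneProfile:
    """Average the 20-window ratio vectors of all elements per class.

    Elements shorter than ``n_windows`` bp cannot be windowed and are
    skipped (logged); classes with no valid element are omitted with a
    warning.
    """
    windows = []
    keys: list[tuple[str, int]] = []  # (class, window index)
    n_valid: dict[str, int] = {}
    n_skipped = 0
    for el in elements:
        try:
            wins = partition_windows(el.interval, n_windows)
        except ValueError:
            n_skipped += 1
            continue
        windows.extend(wins)
        keys.extend((el.element_class, w) for w in range(n_windows))
        n_valid[el.element_class] = n_valid.get(el.element_class, 0) + 1
    if n_skipped:
        logger.info("skipped %d elements shorter than %d bp", n_skipped, n_windows)
    track = methylation_ratio(windows, enriched, unenriched)
    sums: dict[str, np.ndarray] = {
        cls: np.zeros(n_windows) for cls in n_valid
    }
    for (cls, w), ratio in zip(keys, track.ratio):
        sums[cls][w] += ratio
    data = {cls: sums[cls] / n_valid[cls] for cls in sums}
    for cls in ELEMENT_CLASSES:
        if cls not in data:
            logger.warning("element class %s has no valid elements; omitted", cls)
    return MetaGeneProfile(data, n_valid, tissue, n_windows)


@dataclass
class BoundaryProfile:
    """Per-bp mean ratio over [-intron_bp, +exon_bp) around 3' intron/exon
    junctions, gene-oriented (position 0 = first exon base)."""

    values: np.ndarray
    n_junctions: int
    intron_bp: int = 1000
    exon_bp: int = 100

    @property
    def positions(self) -> np.ndarray:
        return np.arange(-self.intron_bp, self.exon_bp)


def boundary_profile(
    genes: Sequence[GeneModel],
    enriched: FragmentSet,
    unenriched: FragmentSet,
    intron_bp: int = 1000,
    exon_bp: int = 100,
    subwindow: int = 50,
) -> BoundaryProfile:
    """Mean ratio across every junction between an intron of >= ``intron_bp``
    and its downstream (3') exon, in fixed ``subwindow``-bp steps expanded to
    per-bp resolution."""
    if (intron_bp + exon_bp) % subwindow:
        raise ValueError("intron_bp + exon_bp must be a multiple of subwindow")
    n_sub = (intron_bp + exon_bp) // subwindow
    windows = []
    n_junctions = 0
    for gene in genes:
        for intron, exon in zip(gene.introns, gene.exons[1:]):
            if intron.length < intron_bp:
                continue
            if gene.strand == "+":
                lo, hi = exon.start - intron_bp, exon.start + exon_bp
                steps = [
                    (lo + k * subwindow, lo + (k + 1) * subwindow)
                    for k in range(n_sub)
                ]
            else:
                lo, hi = exon.end - exon_bp, exon.end + intron_bp
                steps = [
                    (hi - (k + 1) * subwindow, hi - k * subwindow)
                    for k in range(n_sub)
                ]
            if lo < 0:
                continue
            n_junctions += 1
            windows.extend(
                type(gene.interval)(gene.chrom, s, e, gene.strand) for s, e in steps
            )
    if n_junctions == 0:
        logger.warning("no intron of >= %d bp; boundary profile is empty", intron_bp)
        return BoundaryProfile(np.zeros(0), 0, intron_bp, exon_bp)
    track = methylation_ratio(windows, enriched, unenriched)
    per_sub = track.ratio.reshape(n_junctions, n_sub).mean(axis=0)
    return BoundaryProfile(
        np.repeat(per_sub, subwindow), n_junctions, intron_bp, exon_bp
    )


def gene_element_ratios(
    elements: Sequence[MetaGeneElement],
    enriched: FragmentSet,
    unenriched: FragmentSet,
    classes: Sequence[str] | None = None,
    n_windows: int = 20,
) -> pd.DataFrame:
    """Per-gene, per-class methylation summaries.

    ``ratio_whole`` treats the union of a gene's class intervals as a single
    window (counts summed before the ratio); ``ratio_winmean`` is the mean of
    the 20-window ratios.  ``ratio_whole`` is the column used for
    expression correlations.
    """
    wanted = set(classes) if classes is not None else None
    chosen = [
        el for el in elements if wanted is None or el.element_class in wanted
    ]
    ivs = [el.interval for el in chosen]
    e = count_in_windows(ivs, enriched)
    u = count_in_windows(ivs, unenriched)
    df = pd.DataFrame(
        {
            "gene_id": [el.gene_id for el in chosen],
            "element_class": [el.element_class for el in chosen],
            "e": e,
            "u": u,
        }
    )
    grouped = df.groupby(["gene_id", "element_class"], as_index=False).agg(
        e=("e", "sum"), u=("u", "sum")
    )
    grouped["ratio_whole"] = ratio_from_counts(
        grouped["e"].to_numpy(),
        grouped["u"].to_numpy(),
        enriched.total_count,
        unenriched.total_count,
    )
    # window-mean column: 20-window ratios averaged per gene/class
    win_rows = []
    for el in chosen:
        try:
            wins = partition_windows(el.interval, n_windows)
        except ValueError:
            continue
        win_rows.append((el.gene_id, el.element_class, wins))
    all_windows = [w for _, _, wins in win_rows for w in wins]
    if all_windows:
        track = methylation_ratio(all_windows, enriched, unenriched)
        means = []
        pos = 0
        for gid, cls, wins in win_rows:
            means.append((gid, cls, float(track.ratio[pos : pos + len(wins)].mean())))
            pos += len(wins)
        wm = (
            pd.DataFrame(means, columns=["gene_id", "element_class", "ratio_winmean"])
            .groupby(["gene_id", "element_class"], as_index=False)
            .mean()
        )
        grouped = grouped.merge(wm, on=["gene_id", "element_class"], how="left")
    else:
        grouped["ratio_winmean"] = np.nan
    return grouped.drop(columns=["e", "u"])


def stratify_profile_by_decile(
    elements: Sequence[MetaGeneElement],
    enriched: FragmentSet,
    unenriched: FragmentSet,
    expression: pd.DataFrame,
    n_windows: int = 20,
) -> dict[int, MetaGeneProfile]:
    """Meta-gene profiles per expression decile (decile 10 = highest RPKM).

    Only genes with a retained promoter element participate; deciles are
    recomputed on that gene subset by RPKM rank with ties broken by gene_id.
    """
    from .expression import assign_deciles  # local import to avoid a cycle

    with_promoter = {
        el.gene_id for el in elements if el.element_class == "promoter"
    }
    table = expression[expression["gene_id"].isin(with_promoter)].copy()
    if len(table) < 10:
        raise ValueError("need at least 10 genes with promoters and expression")
    table = assign_deciles(table)
    decile_of = dict(zip(table["gene_id"], table["decile"]))
    profiles: dict[int, MetaGeneProfile] = {}
    for decile in range(1, 11):
        genes_in = {g for g, d in decile_of.items() if d == decile}
        subset = [el for el in elements if el.gene_id in genes_in]
        profiles[decile] = metagene_profile(
            subset, enriched, unenriched, n_windows
        )
    return profiles
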