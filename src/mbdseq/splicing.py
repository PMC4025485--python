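"""Skipped-exon detection from splice junctions and methylation contrast.

A splice junction whose two flanks land in (abut or fall within) two exons
of the same gene is a skipping candidate; it is called a skipped exon iff
exactly one annotated exon lies fully inside the junction's intron span.
Junctions spanning zero exons (normal splicing) or two or more exons are
ignored.  The methylation contrast compares shuffle-bootstrap peak
enrichment across the call contexts: skipped exons, the retained flanking
exons, and the intervening introns.
"""

from __future__ import annotations

import logging
from collections.abc import Sequence
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .annotation import GeneModel
from .enrichment import EnrichmentResult, bootstrap_enrichment
from .intervals import GenomeLayout, GenomicInterval, merge_intervals
from .scoring import PeakSet

logger = logging.getLogger(__name__)

_STAR_STRANDS = {0: ".", 1: "+", 2: "-"}


@dataclass(frozen=True)
class SpliceJunction:
    """0-based half-open intron span of a splice junction."""

    chrom: str
    intron_start: int
    intron_end: int
    strand: str = "."
    read_support: int = 1

    def __post_init__(self) -> None:
        if self.intron_end <= self.intron_start:
            raise ValueError("intron_end must exceed intron_start")
        if self.read_support < 1:
            raise ValueError("read_support must be >= 1")


@dataclass(frozen=True)
class SkippedExonCall:
    gene_id: str
    skipped_exon: GenomicInterval
    upstream_exon: GenomicInterval
    downstream_exon: GenomicInterval
    flanking_introns: tuple[GenomicInterval, GenomicInterval]
    junction: SpliceJunction


def read_star_junctions(path: str | Path) -> list[SpliceJunction]:
    """STAR SJ.out.tab dialect: chrom, 1-based intron start/end, strand code
    (0/1/2), motif, annotated, unique reads, multi reads, overhang."""
    out = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 7 or not parts[1].isdigit():
                continue
            support = int(parts[6])
            if support < 1:
                continue
            out.append(
                SpliceJunction(
                    chrom=parts[0],
                    intron_start=int(parts[1]) - 1,
                    intron_end=int(parts[2]),
                    strand=_STAR_STRANDS.get(int(parts[3]), "."),
                    read_support=support,
                )
            )
    return out


def read_junctions_tsv(path: str | Path) -> list[SpliceJunction]:
    """Minimal 5-column TSV: chrom, 0-based start, end (half-open intron
    span), strand, read_support; header optional."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("chrom\t"):
                continue
            chrom, start, end, strand, support = line.split("\t")[:5]
            out.append(
                SpliceJunction(chrom, int(start), int(end), strand, int(support))
            )
    return out


def write_junctions_tsv(junctions: Sequence[SpliceJunction], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tstrand\tread_support\n")
        for j in junctions:
            fh.write(
                f"{j.chrom}\t{j.intron_start}\t{j.intron_end}\t{j.strand}\t{j.read_support}\n"
            )


def _flank_exon(
    exons: Sequence[GenomicInterval], pos: int, side: str, tolerance: int
) -> GenomicInterval | None:
    """Exon whose 3' boundary (side='end') or 5' boundary (side='start')
    abuts ``pos`` within tolerance, or that contains ``pos``."""
    for exon in exons:
        if side == "end":
            if abs(exon.end - pos) <= tolerance or exon.start < pos < exon.end:
                return exon
        else:
            if abs(exon.start - pos) <= tolerance or exon.start < pos < exon.end:
                return exon
    return None


def detect_skipped_exons(
    junctions: Sequence[SpliceJunction],
    genes: Sequence[GeneModel],
    min_support: int = 1,
    tolerance: int = 0,
) -> list[SkippedExonCall]:
    """Call skipped exons (exactly one annotated exon inside the junction).

    Junction flanks must abut (within ``tolerance`` bp) or fall within two
    exons of the same gene; junctions with a strand conflicting the gene's
    are ignored, as are junctions matching no gene (both logged).
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for gene in genes:
        by_chrom.setdefault(gene.chrom, []).append(gene)
    for lst in by_chrom.values():
        lst.sort(key=lambda g: (g.interval.start, g.gene_id))
    calls = []
    n_unmatched = n_strand = 0
    for j in junctions:
        if j.read_support < min_support:
            continue
        matched = False
        for gene in by_chrom.get(j.chrom, ()):
            if gene.interval.start > j.intron_start:
                break
            if gene.interval.end < j.intron_end:
                continue
            if j.strand != "." and j.strand != gene.strand:
                n_strand += 1
                continue
            exons = gene.exons_genomic
            up = _flank_exon(exons, j.intron_start, "end", tolerance)
            down = _flank_exon(exons, j.intron_end, "start", tolerance)
            if up is None or down is None or up == down:
                continue
            matched = True
            inside = [
                e
                for e in exons
                if e.start >= j.intron_start
                and e.end <= j.intron_end
                and e not in (up, down)
            ]
            if len(inside) != 1:
                continue
            skipped = inside[0]
            calls.append(
                SkippedExonCall(
                    gene_id=gene.gene_id,
                    skipped_exon=skipped,
                    upstream_exon=up,
                    downstream_exon=down,
                    flanking_introns=(
                        GenomicInterval(j.chrom, up.end, skipped.start, gene.strand),
                        GenomicInterval(j.chrom, skipped.end, down.start, gene.strand),
                    ),
                    junction=j,
                )
            )
        if not matched:
            n_unmatched += 1
    if n_unmatched:
        logger.info("%d junctions matched no gene or spanned != 1 exon", n_unmatched)
    if n_strand:
        logger.info("%d junction/gene strand conflicts ignored", n_strand)
    return calls


def splice_contexts(
    calls: Sequence[SkippedExonCall],
) -> dict[str, list[GenomicInterval]]:
    """Merged interval sets for the call contexts."""
    skipped, retained, introns = [], [], []
    for call in calls:
        skipped.append(call.skipped_exon)
        retained.extend([call.upstream_exon, call.downstream_exon])
        introns.extend(call.flanking_introns)
    return {
        "skipped_exon": merge_intervals(skipped),
        "retained_exon": merge_intervals(retained),
        "intervening_intron": merge_intervals(introns),
    }


def splice_context_enrichment(
    calls: Sequence[SkippedExonCall],
    peaks: PeakSet,
    layout: GenomeLayout,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> dict[str, EnrichmentResult]:
    """Peak enrichment per splice context (skipped vs retained exons and
    the intervening introns); empty contexts are omitted."""
    if not calls:
        raise ValueError("no skipped-exon calls supplied")
    results = {}
    for i, (name, intervals) in enumerate(splice_contexts(calls).items()):
        if not intervals:
            logger.warning("context %s is empty; omitted", name)
            continue
        results[name] = bootstrap_enrichment(
            peaks,
            intervals,
            layout,
            n_shuffles=n_shuffles,
            seed=seed + i,
            feature_name=name,
        )
    return results


def calls_table(calls: Sequence[SkippedExonCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "gene_id": c.gene_id,
                "chrom": c.skipped_exon.chrom,
                "skipped_start": c.skipped_exon.start,
                "skipped_end": c.skipped_exon.end,
                "upstream_start": c.upstream_exon.start,
                "upstream_end": c.upstream_exon.end,
                "downstream_start": c.downstream_exon.start,
                "downstream_end": c.downstream_exon.end,
                "junction_start": c.junction.intron_start,
                "junction_end": c.junction.intron_end,
                "read_support": c.junction.read_support,
            }
        )
    return pd.DataFrame(rows)
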