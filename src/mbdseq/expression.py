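"""Gene expression quantification and methylation-expression correlation.

RPKM is computed from union-mode exonic fragment counts (a fragment counts
for a gene iff it overlaps that gene's merged exons and no other gene's
exons; ambiguous fragments are discarded).  Genes are ranked into ten
equal-count expression deciles (decile 10 = highest RPKM, ties broken by
gene_id), promoters are classified by CpG-island overlap, and per-element
methylation is correlated with expression by Spearman rank correlation,
optionally split by promoter CpG-island status.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GeneModel, MetaGeneElement
from .intervals import GenomicInterval, MergedIndex, intersect_intervals

logger = logging.getLogger(__name__)


@dataclass
class CorrelationResult:
    element_class: str
    subset: str  # all | cpg_promoter | non_cpg_promoter
    spearman_rho: float
    p_value: float
    n_genes: int
    computed: bool = True


def count_fragments_per_gene(
    fragments: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
) -> tuple[dict[str, int], int, int]:
    """Union-mode exonic counting.

    Returns (counts per gene, total counted, ambiguous discarded).  A
    fragment is ambiguous when it overlaps exons of more than one gene.
    """
    exons: list[GenomicInterval] = []
    exon_gene: list[str] = []
    for gene in genes:
        for exon in gene.exons:
            exons.append(exon)
            exon_gene.append(gene.gene_id)
    gene_sets: dict[int, set[str]] = {}
    for hit in intersect_intervals(fragments, exons):
        gene_sets.setdefault(hit.index_a, set()).add(exon_gene[hit.index_b])
    counts = {g.gene_id: 0 for g in genes}
    ambiguous = 0
    for genes_hit in gene_sets.values():
        if len(genes_hit) == 1:
            counts[next(iter(genes_hit))] += 1
        else:
            ambiguous += 1
    total = sum(counts.values())
    if ambiguous:
        logger.info("discarded %d ambiguous fragments", ambiguous)
    return counts, total, ambiguous


def exonic_length(gene: GeneModel) -> int:
    return sum(e.length for e in gene.exons)


def rpkm(
    counts: Mapping[str, int],
    exonic_lengths: Mapping[str, int],
    total_counted: int,
) -> pd.Series:
    """reads / (exonic kb) / (million counted); zero-length genes excluded."""
    if total_counted <= 0:
        raise ValueError("total_counted must be positive")
    values = {}
    for gene_id, count in counts.items():
        length = exonic_lengths.get(gene_id, 0)
        if length <= 0:
            logger.warning("gene %s has zero exonic length; excluded", gene_id)
            continue
        values[gene_id] = count / (length / 1000) / (total_counted / 1e6)
    return pd.Series(values, name="rpkm")


def build_expression_table(
    counts: Mapping[str, int] | pd.DataFrame,
    genes: Sequence[GeneModel],
) -> pd.DataFrame:
    """(gene_id, count, exonic_bp, rpkm) table from counts + gene models."""
    if isinstance(counts, pd.DataFrame):
        counts = dict(zip(counts["gene_id"], counts["count"]))
    lengths = {g.gene_id: exonic_length(g) for g in genes}
    known = {g: c for g, c in counts.items() if g in lengths}
    total = sum(known.values())
    values = rpkm(known, lengths, total)
    return pd.DataFrame(
        {
            "gene_id": values.index,
            "count": [known[g] for g in values.index],
            "exonic_bp": [lengths[g] for g in values.index],
            "rpkm": values.to_numpy(),
        }
    ).reset_index(drop=True)


def assign_deciles(table: pd.DataFrame, n_bins: int = 10) -> pd.DataFrame:
    """Rank-based equal-count bins (sizes differ by <= 1); bin ``n_bins`` is
    the highest-expressing; ties broken by gene_id for reproducibility."""
    if len(table) < n_bins:
        raise ValueError(f"need at least {n_bins} genes to assign deciles")
    table = table.sort_values(["rpkm", "gene_id"], kind="mergesort").reset_index(
        drop=True
    )
    rank = np.arange(len(table))
    table["decile"] = 1 + (rank * n_bins) // len(table)
    return table.sort_values("gene_id", kind="mergesort").reset_index(drop=True)


def promoter_cpg_status(
    promoters: Mapping[str, GenomicInterval] | Sequence[MetaGeneElement],
    cpg_track: Sequence[GenomicInterval],
) -> dict[str, bool]:
    """True iff the gene's promoter overlaps >= 1 bp of a CpG island."""
    if not isinstance(promoters, Mapping):
        promoters = {
            el.gene_id: el.interval
            for el in promoters
            if el.element_class == "promoter"
        }
    index = MergedIndex(cpg_track)
    out = {}
    for gene_id, iv in promoters.items():
        hit = index.overlaps_any(
            iv.chrom, np.asarray([iv.start]), np.asarray([iv.end])
        )
        out[gene_id] = bool(hit[0])
    return out


def element_expression_correlation(
    element_ratios: pd.DataFrame,
    table: pd.DataFrame,
    promoter_cpg: Mapping[str, bool] | None = None,
    ratio_column: str = "ratio_whole",
    min_genes: int = 10,
) -> list[CorrelationResult]:
    """Spearman correlation of per-gene element methylation with RPKM.

    ``element_ratios`` is the long table from
    :func:`mbdseq.metagene.gene_element_ratios`.  When ``promoter_cpg`` is
    given, correlations are additionally computed within the CpG-island and
    non-CpG promoter subsets.  Subsets below ``min_genes`` are flagged
    not-computed.
    """
    merged = element_ratios.merge(
        table[["gene_id", "rpkm"]], on="gene_id", how="inner"
    )
    subsets: dict[str, pd.DataFrame] = {"all": merged}
    if promoter_cpg is not None:
        has = merged["gene_id"].map(promoter_cpg)
        subsets["cpg_promoter"] = merged[has == True]  # noqa: E712
        subsets["non_cpg_promoter"] = merged[has == False]  # noqa: E712
    results = []
    for subset_name, sub in subsets.items():
        for cls, group in sub.groupby("element_class"):
            group = group.dropna(subset=[ratio_column, "rpkm"])
            n = len(group)
            if n < min_genes:
                results.append(
                    CorrelationResult(cls, subset_name, np.nan, np.nan, n, False)
                )
                continue
            rho, p = stats.spearmanr(group[ratio_column], group["rpkm"])
            results.append(CorrelationResult(cls, subset_name, float(rho), float(p), n))
    return results


def correlation_table(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
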