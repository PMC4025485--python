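"""Gene annotation parsing and derived interval sets.

Builds the interval universe the analyses consume: strand-oriented gene
models with merged exons, the meta-gene element dissection (flanks, promoter,
UTRs, first/last exons, interior-exon quartiles, intron thirds), gene
deserts, and named feature tracks.

Conventions
-----------
* GTF (Ensembl dialect) and GFF3 are accepted; 1-based inclusive coordinates
  are converted to 0-based half-open on read.
* Overlapping exon annotations of the same gene are merged into their union,
  so a gene has one non-redundant exon chain and introns are the gaps.
* Promoters are the 2000 bp 5' of the TSS and are removed when they overlap a
  *different* gene's span; the 10 kb upstream/downstream flanks are removed
  when they overlap *any* gene span.
"""

from __future__ import annotations

import io as _io
import logging
import math
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import gffutils

from .intervals import (
    GenomeLayout,
    GenomicInterval,
    complement_intervals,
    merge_intervals,
    sort_intervals,
)

logger = logging.getLogger(__name__)

ELEMENT_CLASSES = (
    "upstream_10kb",
    "promoter",
    "utr5",
    "first_exon",
    "exon_q1",
    "exon_q2",
    "exon_q3",
    "exon_q4",
    "intron_t1",
    "intron_t2",
    "intron_t3",
    "last_exon",
    "utr3",
    "downstream_10kb",
)

EXON_QUARTILES = ("exon_q1", "exon_q2", "exon_q3", "exon_q4")
INTRON_THIRDS = ("intron_t1", "intron_t2", "intron_t3")


class AnnotationParseError(ValueError):
    """Malformed GTF/GFF3 record, reported with its line number."""


@dataclass(frozen=True)
class GeneModel:
    """A gene's strand-oriented anatomy.

    ``exons`` and ``introns`` are ordered 5' -> 3' along the gene (reversed
    genomic order on the minus strand); ``tss`` is the gene start on the plus
    strand and the gene end on the minus strand.
    """

    gene_id: str
    interval: GenomicInterval
    strand: str
    exons: tuple[GenomicInterval, ...]
    introns: tuple[GenomicInterval, ...]
    utr5: tuple[GenomicInterval, ...] = ()
    utr3: tuple[GenomicInterval, ...] = ()

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end

    @property
    def tes(self) -> int:
        return self.interval.end if self.strand == "+" else self.interval.start

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def exons_genomic(self) -> tuple[GenomicInterval, ...]:
        return tuple(sorted(self.exons, key=lambda iv: iv.start))


@dataclass(frozen=True)
class MetaGeneElement:
    gene_id: str
    element_class: str
    interval: GenomicInterval
    strand: str


@dataclass
class FeatureTrack:
    """A named interval set (CpG islands, repeat classes, histone peaks...)."""

    name: str
    intervals: list[GenomicInterval] = field(default_factory=list)


def build_gene_model(
    gene_id: str,
    chrom: str,
    strand: str,
    exons: Iterable[GenomicInterval],
    utr5: Iterable[GenomicInterval] = (),
    utr3: Iterable[GenomicInterval] = (),
) -> GeneModel:
    """Merge exon annotations and derive introns for one gene."""
    merged = merge_intervals(exons)
    if not merged:
        raise ValueError(f"gene {gene_id} has no exons")
    span = GenomicInterval(chrom, merged[0].start, merged[-1].end, strand)
    introns = [
        GenomicInterval(chrom, a.end, b.start, strand)
        for a, b in zip(merged, merged[1:])
    ]
    merged = [GenomicInterval(chrom, iv.start, iv.end, strand) for iv in merged]
    if strand == "-":
        merged = merged[::-1]
        introns = introns[::-1]
    return GeneModel(
        gene_id=gene_id,
        interval=span,
        strand=strand,
        exons=tuple(merged),
        introns=tuple(introns),
        utr5=tuple(
            GenomicInterval(chrom, iv.start, iv.end, strand)
            for iv in merge_intervals(utr5)
        ),
        utr3=tuple(
            GenomicInterval(chrom, iv.start, iv.end, strand)
            for iv in merge_intervals(utr3)
        ),
    )


def _validate_lines(text: str, origin: str) -> None:
    for ln, line in enumerate(text.splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 8:
            raise AnnotationParseError(
                f"{origin}:{ln}: expected >= 8 tab-separated fields"
            )
        try:
            start, end = int(parts[3]), int(parts[4])
        except ValueError as exc:
            raise AnnotationParseError(
                f"{origin}:{ln}: non-integer coordinates"
            ) from exc
        if start < 1 or end < start:
            raise AnnotationParseError(
                f"{origin}:{ln}: bad coordinate range {start}-{end}"
            )


def _gene_id_of(db: gffutils.FeatureDB, feat, cache: dict[str, str]) -> str | None:
    if "gene_id" in feat.attributes:
        return feat.attributes["gene_id"][0]
    # GFF3: climb Parent links (exon -> transcript -> gene)
    key = feat.attributes.get("Parent", [feat.id])[0]
    if key in cache:
        return cache[key]
    current = feat
    for _ in range(4):
        parents = list(db.parents(current, level=1))
        if not parents:
            break
        current = parents[0]
    gid = current.id if current is not feat else None
    if gid is not None:
        cache[key] = gid
    return gid


def read_gene_annotation(
    source: str | Path | _io.TextIOBase, layout: GenomeLayout
) -> list[GeneModel]:
    """Parse GTF/GFF3 into merged-exon gene models.

    Records whose exon lies outside the chromosome bounds of ``layout`` are
    rejected and logged; malformed lines raise :class:`AnnotationParseError`
    with the offending line number.
    """
    looks_like_path = isinstance(source, (str, Path)) and "\n" not in str(source)
    if looks_like_path and Path(str(source)).exists():
        text = Path(source).read_text()
        origin = str(source)
    elif hasattr(source, "read"):
        text = source.read()
        origin = "<stream>"
    else:
        text = str(source)
        origin = "<string>"
    _validate_lines(text, origin)
    db = gffutils.create_db(
        text,
        dbfn=":memory:",
        from_string=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        keep_order=False,
    )
    exons: dict[str, list[GenomicInterval]] = {}
    utr5: dict[str, list[GenomicInterval]] = {}
    utr3: dict[str, list[GenomicInterval]] = {}
    strands: dict[str, str] = {}
    cache: dict[str, str] = {}
    rejected = 0
    for feat in db.all_features():
        ftype = feat.featuretype.lower()
        if ftype not in ("exon", "five_prime_utr", "three_prime_utr"):
            continue
        gid = _gene_id_of(db, feat, cache)
        if gid is None:
            rejected += 1
            continue
        iv_start, iv_end = feat.start - 1, feat.end  # 1-based inclusive -> half-open
        if feat.seqid not in layout or iv_end > layout.length_of(feat.seqid):
            rejected += 1
            continue
        strand = feat.strand if feat.strand in ("+", "-") else "."
        strands.setdefault(gid, strand)
        iv = GenomicInterval(feat.seqid, iv_start, iv_end, strand)
        target = {"exon": exons, "five_prime_utr": utr5, "three_prime_utr": utr3}[ftype]
        target.setdefault(gid, []).append(iv)
    if rejected:
        logger.warning("rejected %d out-of-bounds or orphan records", rejected)
    genes = []
    for gid in sorted(exons):
        ivs = exons[gid]
        genes.append(
            build_gene_model(
                gid,
                ivs[0].chrom,
                strands[gid],
                ivs,
                utr5.get(gid, ()),
                utr3.get(gid, ()),
            )
        )
    return genes


def write_gtf(genes: Sequence[GeneModel], path: str | Path | None = None) -> str:
    """Serialize gene models as Ensembl-dialect GTF (deterministic order)."""
    lines: list[str] = []

    def rec(gene: GeneModel, ftype: str, iv: GenomicInterval) -> str:
        attrs = f'gene_id "{gene.gene_id}"; transcript_id "{gene.gene_id}.t1";'
        return (
            f"{iv.chrom}\tmbdseq\t{ftype}\t{iv.start + 1}\t{iv.end}\t.\t"
            f"{gene.strand}\t.\t{attrs}"
        )

    for gene in genes:
        lines.append(rec(gene, "gene", gene.interval))
        lines.append(rec(gene, "transcript", gene.interval))
        for exon in gene.exons_genomic:
            lines.append(rec(gene, "exon", exon))
        for iv in gene.utr5:
            lines.append(rec(gene, "five_prime_utr", iv))
        for iv in gene.utr3:
            lines.append(rec(gene, "three_prime_utr", iv))
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def _overlaps_other_gene(
    candidate: GenomicInterval,
    gene_id: str,
    spans_by_chrom: dict[str, list[tuple[int, int, str]]],
    include_own: bool = False,
) -> bool:
    for start, end, gid in spans_by_chrom.get(candidate.chrom, ()):
        if not include_own and gid == gene_id:
            continue
        if start < candidate.end and candidate.start < end:
            return True
    return False


def ordinal_bin(i: int, n: int, bins: int) -> int:
    """1-based bin of the i-th (1-based) of n items split into ``bins`` ordinal
    groups: ``ceil(bins * i / n)``."""
    return math.ceil(bins * i / n)


def build_metagene_elements(
    genes: Sequence[GeneModel],
    layout: GenomeLayout,
    promoter_bp: int = 2000,
    flank_bp: int = 10000,
) -> list[MetaGeneElement]:
    """Dissect every gene into meta-gene element intervals.

    Promoters are truncated at chromosome edges and dropped when overlapping a
    different gene's span; upstream/downstream flanks are dropped when
    overlapping any gene span.  Interior exons get ordinal quartile labels,
    introns ordinal third labels; single-exon genes contribute only a
    ``first_exon``.
    """
    spans_by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for g in genes:
        spans_by_chrom.setdefault(g.chrom, []).append(
            (g.interval.start, g.interval.end, g.gene_id)
        )
    elements: list[MetaGeneElement] = []
    n_single = n_prom_dropped = n_flank_dropped = 0

    def add(gene: GeneModel, cls: str, iv: GenomicInterval | None) -> None:
        if iv is not None:
            elements.append(MetaGeneElement(gene.gene_id, cls, iv, gene.strand))

    for gene in genes:
        chrom, strand = gene.chrom, gene.strand
        if strand == "+":
            prom = layout.clip(chrom, gene.tss - promoter_bp, gene.tss, strand)
            up = layout.clip(
                chrom, gene.tss - promoter_bp - flank_bp, gene.tss - promoter_bp, strand
            )
            down = layout.clip(chrom, gene.tes, gene.tes + flank_bp, strand)
        else:
            prom = layout.clip(chrom, gene.tss, gene.tss + promoter_bp, strand)
            up = layout.clip(
                chrom, gene.tss + promoter_bp, gene.tss + promoter_bp + flank_bp, strand
            )
            down = layout.clip(chrom, gene.tes - flank_bp, gene.tes, strand)
        if prom is not None and _overlaps_other_gene(prom, gene.gene_id, spans_by_chrom):
            prom = None
            n_prom_dropped += 1
        add(gene, "promoter", prom)
        for cls, flank in (("upstream_10kb", up), ("downstream_10kb", down)):
            if flank is not None and _overlaps_other_gene(
                flank, gene.gene_id, spans_by_chrom, include_own=True
            ):
                flank = None
                n_flank_dropped += 1
            add(gene, cls, flank)
        for iv in gene.utr5:
            add(gene, "utr5", iv)
        for iv in gene.utr3:
            add(gene, "utr3", iv)
        add(gene, "first_exon", gene.exons[0])
        if gene.n_exons == 1:
            n_single += 1
            continue
        add(gene, "last_exon", gene.exons[-1])
        interior = gene.exons[1:-1]
        for i, exon in enumerate(interior, 1):
            add(gene, EXON_QUARTILES[ordinal_bin(i, len(interior), 4) - 1], exon)
        for i, intron in enumerate(gene.introns, 1):
            add(gene, INTRON_THIRDS[ordinal_bin(i, len(gene.introns), 3) - 1], intron)
    if n_single:
        logger.info("%d single-exon genes contribute only a first_exon", n_single)
    logger.info(
        "dropped %d promoters and %d flanks overlapping genes",
        n_prom_dropped,
        n_flank_dropped,
    )
    return elements


def elements_by_class(
    elements: Iterable[MetaGeneElement],
) -> dict[str, list[MetaGeneElement]]:
    out: dict[str, list[MetaGeneElement]] = {}
    for el in elements:
        out.setdefault(el.element_class, []).append(el)
    return out


def build_gene_deserts(
    genes: Sequence[GeneModel],
    layout: GenomeLayout,
    min_distance: int = 250_000,
) -> list[GenomicInterval]:
    """Regions farther than ``min_distance`` bp from any gene span."""
    if not genes:
        raise ValueError("no genes provided")
    padded = []
    for g in genes:
        iv = layout.clip(
            g.chrom, g.interval.start - min_distance, g.interval.end + min_distance
        )
        if iv is not None:
            padded.append(iv)
    # chromosomes with no genes are entirely desert
    return sort_intervals(complement_intervals(padded, layout))
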