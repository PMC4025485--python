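"""Annotation parsing, meta-gene element dissection, and gene deserts."""

import math

import pytest

from mbdseq.annotation import (
    AnnotationParseError,
    build_gene_deserts,
    build_gene_model,
    build_metagene_elements,
    elements_by_class,
    ordinal_bin,
    read_gene_annotation,
    write_gtf,
)
from mbdseq.intervals import GenomeLayout, GenomicInterval


def gtf_line(chrom, feature, start1, end1, strand, gene_id):
    return (
        f"{chrom}\ttest\t{feature}\t{start1}\t{end1}\t.\t{strand}\t.\t"
        f'gene_id "{gene_id}"; transcript_id "{gene_id}.t1";'
    )


@pytest.fixture()
def layout():
    return GenomeLayout({"chr1": 100_000})


class TestReadAnnotation:
    def test_single_gene_exons_and_derived_intron(self, layout):
        text = "\n".join(
            [
                gtf_line("chr1", "exon", 101, 200, "+", "gA"),
                gtf_line("chr1", "exon", 301, 400, "+", "gA"),
            ]
        )
        (gene,) = read_gene_annotation(text, layout)
        assert [(e.start, e.end) for e in gene.exons] == [(100, 200), (300, 400)]
        assert [(i.start, i.end) for i in gene.introns] == [(200, 300)]
        assert (gene.tss, gene.tes) == (100, 400)

    def test_overlapping_transcript_exons_merge_to_union(self, layout):
        text = "\n".join(
            [
                gtf_line("chr1", "exon", 101, 200, "+", "gA"),
                gtf_line("chr1", "exon", 151, 250, "+", "gA"),
            ]
        )
        (gene,) = read_gene_annotation(text, layout)
        assert [(e.start, e.end) for e in gene.exons] == [(100, 250)]

    def test_minus_strand_exons_are_5prime_first(self, layout):
        text = "\n".join(
            [
                gtf_line("chr1", "exon", 101, 200, "-", "gA"),
                gtf_line("chr1", "exon", 301, 400, "-", "gA"),
            ]
        )
        (gene,) = read_gene_annotation(text, layout)
        assert gene.exons[0].start == 300  # 5'-most on minus strand
        assert gene.tss == 400

    def test_malformed_record_reports_line_number(self, layout):
        text = gtf_line("chr1", "exon", 101, 200, "+", "gA") + "\nchr1\tbroken"
        with pytest.raises(AnnotationParseError, match=":2:"):
            read_gene_annotation(text, layout)

    def test_out_of_bounds_exon_rejected(self, layout):
        text = "\n".join(
            [
                gtf_line("chr1", "exon", 101, 200, "+", "gA"),
                gtf_line("chr1", "exon", 200_001, 200_100, "+", "gB"),
            ]
        )
        genes = read_gene_annotation(text, layout)
        assert [g.gene_id for g in genes] == ["gA"]

    def test_random_genes_match_per_base_union_oracle(self, rng, layout):
        lines = []
        truth = {}
        for k in range(50):
            gid = f"g{k:03d}"
            occupancy = set()
            for _ in range(int(rng.integers(1, 6))):
                start = int(rng.integers(0, 90_000))
                length = int(rng.integers(1, 500))
                occupancy.update(range(start, start + length))
                lines.append(gtf_line("chr1", "exon", start + 1, start + length, "+", gid))
            truth[gid] = occupancy
        genes = read_gene_annotation("\n".join(lines), layout)
        assert len(genes) == 50
        for gene in genes:
            bases = set()
            for e in gene.exons:
                assert not bases & set(range(e.start, e.end))  # merged: disjoint
                bases.update(range(e.start, e.end))
            assert bases == truth[gene.gene_id]
            intron_bases = set()
            for i in gene.introns:
                intron_bases.update(range(i.start, i.end))
            span = set(range(gene.interval.start, gene.interval.end))
            assert intron_bases == span - bases

    def test_gff3_dialect_with_parent_links(self, layout):
        gff = "\n".join(
            [
                "##gff-version 3",
                "chr1\ttest\tgene\t101\t400\t.\t+\t.\tID=geneA",
                "chr1\ttest\tmRNA\t101\t400\t.\t+\t.\tID=tA;Parent=geneA",
                "chr1\ttest\texon\t101\t200\t.\t+\t.\tID=eA1;Parent=tA",
                "chr1\ttest\texon\t301\t400\t.\t+\t.\tID=eA2;Parent=tA",
                "chr1\ttest\tfive_prime_UTR\t101\t130\t.\t+\t.\tID=u5;Parent=tA",
            ]
        )
        (gene,) = read_gene_annotation(gff, layout)
        assert gene.gene_id == "geneA"
        assert [(e.start, e.end) for e in gene.exons] == [(100, 200), (300, 400)]
        assert [(i.start, i.end) for i in gene.introns] == [(200, 300)]
        assert [(u.start, u.end, u.strand) for u in gene.utr5] == [(100, 130, "+")]

    def test_gtf_roundtrip(self, layout):
        gene = build_gene_model(
            "gA",
            "chr1",
            "-",
            [GenomicInterval("chr1", 100, 300, "-"), GenomicInterval("chr1", 500, 700, "-")],
            utr5=[GenomicInterval("chr1", 650, 700, "-")],
            utr3=[GenomicInterval("chr1", 100, 150, "-")],
        )
        (back,) = read_gene_annotation(write_gtf([gene]), layout)
        assert back == gene


class TestMetaGeneElements:
    def make_gene(self, start, end, strand, gene_id="gA", n_exons=1):
        length = (end - start) // (2 * n_exons - 1)
        exons = [
            GenomicInterval("chr1", start + 2 * i * length,
                            start + 2 * i * length + length, strand)
            for i in range(n_exons)
        ]
        exons[-1] = GenomicInterval("chr1", exons[-1].start, end, strand)
        return build_gene_model(gene_id, "chr1", strand, exons)

    def test_promoter_positions_by_strand(self, layout):
        plus = self.make_gene(5000, 9000, "+")
        minus = self.make_gene(5000, 9000, "-", gene_id="gB")
        by_cls = elements_by_class(build_metagene_elements([plus], layout))
        (prom,) = by_cls["promoter"]
        assert (prom.interval.start, prom.interval.end) == (3000, 5000)
        by_cls = elements_by_class(build_metagene_elements([minus], layout))
        (prom,) = by_cls["promoter"]
        assert (prom.interval.start, prom.interval.end) == (9000, 11000)

    def test_promoter_dropped_when_overlapping_other_gene(self, layout):
        gene = self.make_gene(5000, 9000, "+")
        blocker = self.make_gene(2000, 4000, "+", gene_id="gB")
        by_cls = elements_by_class(build_metagene_elements([gene, blocker], layout))
        assert {el.gene_id for el in by_cls["promoter"]} == {"gB"}

    def test_flank_dropped_when_overlapping_any_gene(self, layout):
        gene = self.make_gene(20_000, 24_000, "+")
        neighbour = self.make_gene(10_000, 12_000, "+", gene_id="gB")  # in upstream_10kb
        by_cls = elements_by_class(build_metagene_elements([gene, neighbour], layout))
        assert "gA" not in {el.gene_id for el in by_cls.get("upstream_10kb", [])}

    def test_promoter_truncated_at_chromosome_edge(self, layout):
        gene = self.make_gene(500, 2000, "+")
        by_cls = elements_by_class(build_metagene_elements([gene], layout))
        (prom,) = by_cls["promoter"]
        assert (prom.interval.start, prom.interval.end) == (0, 500)

    @pytest.mark.parametrize(
        "n_interior,expected",
        [
            (4, ["exon_q1", "exon_q2", "exon_q3", "exon_q4"]),
            (8, ["exon_q1", "exon_q1", "exon_q2", "exon_q2",
                 "exon_q3", "exon_q3", "exon_q4", "exon_q4"]),
            (1, ["exon_q4"]),
        ],
    )
    def test_interior_exon_quartiles_follow_ceil_rule(self, layout, n_interior, expected):
        gene = self.make_gene(10_000, 40_000, "+", n_exons=n_interior + 2)
        elements = build_metagene_elements([gene], layout)
        got = [
            el.element_class
            for el in elements
            if el.element_class.startswith("exon_q")
        ]
        assert got == expected
        assert [ordinal_bin(i, n_interior, 4) for i in range(1, n_interior + 1)] == [
            math.ceil(4 * i / n_interior) for i in range(1, n_interior + 1)
        ]

    def test_single_exon_gene_contributes_only_first_exon(self, layout):
        gene = self.make_gene(10_000, 11_000, "+")
        classes = {el.element_class for el in build_metagene_elements([gene], layout)}
        assert "first_exon" in classes
        assert "last_exon" not in classes
        assert not any(c.startswith(("exon_q", "intron_t")) for c in classes)

    def test_gene_body_partition(self, dataset, elements):
        """First exon + interior quartiles + last exon + intron thirds cover
        every gene-body base exactly once."""
        body_classes = {"first_exon", "last_exon", "exon_q1", "exon_q2",
                        "exon_q3", "exon_q4", "intron_t1", "intron_t2", "intron_t3"}
        by_gene = {}
        for el in elements:
            if el.element_class in body_classes:
                by_gene.setdefault(el.gene_id, []).append(el.interval)
        for gene in dataset.genes[:40]:
            parts = by_gene[gene.gene_id]
            assert sum(p.length for p in parts) == gene.interval.length
            covered = set()
            for p in parts:
                block = set(range(p.start, p.end))
                assert not covered & block
                covered |= block


class TestGeneDeserts:
    def test_single_gene_complement(self):
        layout = GenomeLayout({"chr1": 600_000})
        gene = build_gene_model(
            "gA", "chr1", "+", [GenomicInterval("chr1", 0, 1000, "+")]
        )
        deserts = build_gene_deserts([gene], layout)
        assert [(d.start, d.end) for d in deserts] == [(251_000, 600_000)]

    def test_saturated_genome_has_no_deserts(self):
        layout = GenomeLayout({"chr1": 1_000_000})
        genes = [
            build_gene_model(
                f"g{i}", "chr1", "+",
                [GenomicInterval("chr1", i * 100_000, i * 100_000 + 1000, "+")],
            )
            for i in range(10)
        ]
        assert build_gene_deserts(genes, layout) == []

    def test_matches_per_base_distance_oracle(self, rng):
        layout = GenomeLayout({"chr1": 3_000_000})
        step = 1000  # distance oracle on a 1 kb lattice for speed
        genes = []
        for i in range(4):
            start = int(rng.integers(0, 2_900)) * step
            genes.append(
                build_gene_model(
                    f"g{i}", "chr1", "+",
                    [GenomicInterval("chr1", start, start + 5 * step, "+")],
                )
            )
        deserts = build_gene_deserts(genes, layout, min_distance=250_000)
        desert_points = set()
        for d in deserts:
            desert_points.update(range(d.start + step // 2, d.end, step))
        for point in range(step // 2, 3_000_000, step):
            dist = min(
                0 if g.interval.start <= point < g.interval.end
                else min(abs(point - g.interval.start), abs(point - (g.interval.end - 1)))
                for g in genes
            )
            assert (dist > 250_000) == (point in desert_points), point
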