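# mbdseq

Downstream analysis of **MBD-seq** (methyl-CpG binding domain capture
sequencing) experiments: genome-wide CpG methylation maps built from a
methylation-enriched library and its unenriched flow-through, integrated
with gene annotation, chromatin features, expression, and splicing.

The package is aimed at epigenomics analysts who have already aligned reads
and called peaks (e.g. with BWA + MACS2) and need the statistical layer on
top: methylation scoring, enrichment testing, segmentation, and
expression/splicing integration — plus a synthetic study generator with
planted ground truth so every stage can be validated end to end.

## What it computes

**Methylation ratio score.** For a window *w*, with *e*/*u* the fragments of
the enriched / flow-through library overlapping *w* and *E*/*U* the library
totals,

```
ratio(w) = (e / E) / (u / U)
```

a normalized density ratio analogous to RPKM (when *u* = 0 and *e* > 0 a
half-count replaces *u*; windows with *e* = 0 score 0).

**Meta-gene profile.** Each gene is dissected into elements — 10 kb flanks,
a 2 kb promoter 5′ of the TSS (dropped when overlapping another gene), UTRs,
first and last exons, interior exons in ordinal quartiles, introns in
ordinal thirds — each element split into 20 windows (5% of its length) and
ratios averaged per element class across the genome.

**Shuffle-bootstrap enrichment.** The number of peaks (canonicalized to
center ± 100 bp) overlapping a feature track, divided by the mean of that
count over 1000 uniform random re-placements of the peaks; the null
distribution also yields an SD and an empirical p-value with floor
1/(B + 1).

**Two-state segmentation.** Enriched-fragment counts on a 200 bp grid are
binarized against a Poisson background (upper tail p < 1e-4), a two-state
Bernoulli HMM is fitted per tissue by Baum–Welch, and the smoothed posterior
probability of the methylated state is decoded per window. Posteriors from
several tissues are clustered with k-means (k = 14 by default) and each
cluster is assayed for feature enrichment and per-tissue signal proportions.

**Expression and splicing integration.** Union-mode exonic counting → RPKM →
expression deciles; Spearman correlation of per-element methylation with
expression, split by promoter CpG-island status; skipped-exon detection from
splice junctions (exactly one annotated exon between the two junction-flank
exons) with peak-enrichment contrast of skipped vs retained exons.

## Worked example

```python
from mbdseq.simulate import SimulationConfig, simulate_dataset
from mbdseq.annotation import build_metagene_elements
from mbdseq.metagene import metagene_profile
from mbdseq.enrichment import bootstrap_enrichment
from mbdseq.scoring import expand_peaks

config = SimulationConfig(seed=7)          # 4 x 2 Mb genome, 300 genes, 4 tissues
dataset = simulate_dataset(config)
brain = dataset.tissues["brain"]

peaks = expand_peaks(brain.peaks, dataset.layout)
print(f"{len(peaks)} methylation peaks (center +/- 100 bp) in brain")
for name in ("cpg_island", "LTR", "SINE"):
    res = bootstrap_enrichment(peaks, dataset.feature_tracks[name],
                               dataset.layout, n_shuffles=1000, seed=0)
    print(f"{name:>10}: enrichment {res.enrichment:.2f} "
          f"(null {res.null_mean:.0f} +/- {res.null_sd:.0f}, p = {res.empirical_p:.3g})")

elements = build_metagene_elements(dataset.genes, dataset.layout)
profile = metagene_profile(elements, brain.enriched, brain.unenriched)
for cls in ("promoter", "first_exon", "exon_q1", "exon_q4", "last_exon"):
    print(f"{cls:>10}: mean ratio {profile.class_mean(cls):.2f} "
          f"over {profile.n_elements[cls]} elements")
```

prints

```
2193 methylation peaks (center +/- 100 bp) in brain
cpg_island: enrichment 3.18 (null 44 +/- 6, p = 0.000999)
       LTR: enrichment 2.99 (null 134 +/- 11, p = 0.000999)
      SINE: enrichment 0.38 (null 302 +/- 17, p = 0.000999)
  promoter: mean ratio 0.64 over 300 elements
first_exon: mean ratio 7.00 over 300 elements
   exon_q1: mean ratio 1.99 over 207 elements
   exon_q4: mean ratio 3.03 over 412 elements
 last_exon: mean ratio 6.26 over 300 elements
```

Peaks concentrate in CpG islands and LTRs and avoid SINEs; the meta-gene
shows the promoter dip, the 5′→3′ rise across interior exon quartiles, and
the strong last-exon methylation — all effects planted by the generator and
recovered by the pipeline.

## Command line

Every stage is also a subcommand of the `mbdseq` console script —
`simulate`, `elements`, `score`, `metagene`, `enrich`, `segment`, `cluster`,
`correlate`, `splice`, `compare-peaks` — reading and writing standard text
formats (chrom.sizes, GTF/GFF3, BED/narrowPeak, bedGraph, TSV) and appending
a reproducibility manifest (arguments, input checksums, seed, version) to
`manifest.json` in the output directory. Example:

```bash
mbdseq simulate --seed 7 --outdir run
mbdseq enrich --peaks run/brain/peaks.bed --features cpg=run/cpg_island.bed \
    --genome run/chrom.sizes --shuffles 1000 --seed 1 --out run/enrichment.tsv
```

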