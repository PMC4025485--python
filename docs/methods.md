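# Methods

This note documents the statistical model behind each stage, the synthetic
study generator and what it does and does not emulate, and the numerical
choices a maintainer would want to know. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Methylation ratio score

MBD capture partitions sonicated genomic DNA (~300 bp fragments) into a
methylation-enriched fraction and an unenriched flow-through. The score for
a window is the ratio of library-normalized fragment densities,
`(e/E) / (u/U)`. Choices:

* **Counting unit** — a fragment counts for a window when it overlaps it by
  ≥ 1 bp. With 300 bp fragments and windows as small as 5% of a short
  element, 5′-end or midpoint counting would make most fine windows empty;
  overlap counting is the stable choice, at the cost of smoothing the signal
  over roughly a fragment length. This is why sub-exon structure (the
  cap-shaped within-exon profile) sits at the edge of detectability: a
  300 bp fragment spans a whole 150–400 bp exon, so intra-exon contrasts are
  attenuated toward the element mean.
* **Zero flow-through** — when `u = 0` and `e > 0` the denominator count is
  replaced by 0.5 (a half fragment), keeping ratios finite without masking
  real signal; when `e = 0` the ratio is 0. The half-count is anchored to
  the count scale, so exact scale invariance of the ratio holds only where
  the pseudocount does not trigger.
* **Bias** — a ratio of small counts has an `O(1/u)` upward Jensen bias; on
  a flat methylome the profile centers slightly above 1. Comparisons in this
  package are always between classes scored the same way, so the bias
  cancels to first order.
* No CpG-content correction is applied; a config flag is reserved but
  unimplemented.

## Meta-gene construction

Gene models come from GTF/GFF3 (Ensembl dialect; 1-based inclusive
converted to 0-based half-open on read). Overlapping exon annotations of a
gene are merged to their union; introns are the gaps. Elements per gene:

* promoter: 2000 bp 5′ of the TSS, truncated at chromosome edges, dropped
  when overlapping a *different* gene's span (whether the original filter
  also removed promoters overlapping the gene's own body is ambiguous for
  TSS-internal annotations; "different gene" was chosen);
* upstream/downstream flanks: 10 kb beyond the promoter / beyond the gene's
  3′ end, dropped when overlapping *any* gene span;
* first and last exon set aside; interior exons labelled with ordinal
  quartiles `ceil(4·i/n)` and introns with ordinal thirds `ceil(3·i/n)`.
  The ordinal rule (by index, not by bp midpoint) was chosen because the
  profile bins exons, not bases; with fewer interior exons than bins some
  bins are empty, and a single interior exon lands in the last bin by the
  same rule. Single-exon genes contribute only a `first_exon` (tie broken
  toward first).

Each element is split into 20 contiguous windows (widths within 1 bp,
remainder spread from the 5′ end; on the minus strand window 0 is the
genomic-rightmost). Profiles average per-element window vectors with equal
weight per element so long genes do not dominate. Elements shorter than
20 bp cannot form windows and are skipped with a log message.

The intron/exon boundary profile averages the ratio over [−1000, +100) bp
around each junction between an intron of ≥ 1 kb and its downstream (3′)
exon, gene-oriented, scored in 50 bp sub-windows and expanded to per-bp
resolution. The 3′ junction was chosen because the downstream exon's start
is where methylation steps up in the planted model; the measurement is
symmetric code-wise and easy to re-aim.

## Shuffle-bootstrap enrichment

The observed statistic is the **number of peaks** overlapping the feature by
≥ 1 bp (not overlap bp, not feature count) — the simplest reading of a
peak/feature intersection count. The null re-places every peak uniformly:
chromosome chosen with probability ∝ length among chromosomes long enough,
start uniform, length preserved, overlaps permitted (an exclusion track is
accepted and honoured by rejection sampling). Each of the B shuffles uses an
RNG stream spawned deterministically from the root seed, so results do not
depend on evaluation order or parallelism.

Reported: enrichment = observed / null mean; the null SD both on the count
scale and rescaled to the enrichment ratio (`sd/null_mean`, the error-bar
convention); one-sided empirical p in the direction of the effect and a
two-sided p (twice the smaller tail, capped at 1), both with the add-one
rule so the floor is 1/(B+1); and a Monte-Carlo SE of the ratio
(`enrichment · sd/(null_mean·√B)`) used for splice-context error bars. A
feature covering the whole genome yields enrichment exactly 1 with zero SD;
a zero null mean yields infinite enrichment with a warning.

## Two-state segmentation and clustering

Binarization: `call = 1` iff the 200 bp-window enriched-fragment count
reaches the smallest `c` with `P(X ≥ c) < 1e-4` for `X ~ Poisson(λ)`, λ the
genome-wide mean count per window. The HMM is a two-state Bernoulli chain
fitted by Baum–Welch with chromosomes as independent sequences; the
log-likelihood is asserted non-decreasing every iteration; convergence at
|Δll| < 1e-6 or 500 iterations; emissions floored at 1e-6 so degenerate
all-identical tracks remain valid. States are relabelled so state 1 has the
higher emission probability ("methylated"). Forward–backward uses per-step
scaling (normalized α/β) — numerically equivalent to log-space recursions —
with the sequential recursions numba-compiled. Smoothed posteriors
`P(methylated | all calls)` per window feed a windows × tissues matrix.

Clustering is Euclidean k-means on raw posteriors (entries already in
[0, 1]), k-means++ initialization, best of 12 restarts by inertia,
deterministic under the seed; k = 14 by default. Each tissue gets its own
HMM fit. Per-cluster composition runs the bootstrap enrichment on the
cluster's window coordinates per feature track; per-tissue signal
proportions use posterior > 0.5 as the "methylated region" definition and
sum to 1 per tissue. Cross-tissue sharing between tissues a and b is
`Σ_c min(n_a(c), n_b(c)) / max(N_a, N_b)` over clusters, with `n_t(c)` the
high-posterior windows of tissue t in cluster c — a cluster-mediated overlap
in [0, 1].

## Expression and splicing

Union-mode counting: a fragment counts for a gene iff it overlaps that
gene's merged exons and no other gene's (ambiguous fragments discarded).
RPKM = count / (exonic kb) / (million counted); no expression-level
normalization beyond that is applied. Deciles are rank-based equal-count
bins (ties broken by gene id; decile 10 = highest). Element methylation is
summarized per gene both as a whole-element single-window ratio (counts
summed over the class's intervals before the ratio) and as the mean of the
20 window ratios; the whole-element column is used for correlations, both
are emitted. Spearman ρ with the asymptotic t-approximation p-value is
computed per element class, for all genes with a retained promoter and
within CpG-island / non-CpG promoter subsets (promoter CpG status = ≥ 1 bp
island overlap); subsets under 10 genes are flagged not computed.

Skipped exons: a junction's flanks must abut (within a configurable
tolerance, default 0 bp — junction coordinates from spliced aligners are
exact intron bounds) or fall within two exons of the same gene; a call is
made iff exactly one annotated exon lies fully inside the intron span.
Junctions conflicting with the gene's strand are ignored; unknown-strand
junctions are accepted. Contexts (skipped exons, retained flanking exons,
intervening introns) are merged interval sets run through the bootstrap
enrichment; error bars use the Monte-Carlo SE above.

## Synthetic study generator

The generator emits a complete miniature study — genome layout, gene models
with UTRs, CpG-island and LINE/SINE/LTR tracks, per-tissue methylomes,
fragment libraries, peak calls, expression counts, splice junctions — with
recorded truth. Default scale: 4 chromosomes × 2 Mb, 300 non-overlapping
genes (2–10 exons of 150–400 bp, introns 200–2000 bp), 2×10⁵ fragments per
library, four tissues (two embryonic, two terminal). These sizes keep the
full test suite within a few minutes on one CPU while leaving every planted
effect statistically resolvable.

**Methylome.** A per-100 bp-region probability map:
`base_rate (0.15) × element multipliers × repeat/tissue multipliers ×
lognormal region noise (σ = 0.25)`. Planted effects: promoter × 0.25;
cap-shaped within-exon multiplier `1 + amp(6t(1−t) − 1)` (unit mean,
amp = 0.6); linear 5′→3′ gradient 1 → 1.6 across the gene body; last exon
× 2.0, exempted from the gradient (it carries `boost × mean(gradient)`
instead) and extended one region past its boundaries so that the planted
2× effect is what a fragment/peak-level measurement sees rather than a
gradient-compounded, boundary-blurred version; CpG islands × 5; LTR × 3;
LINE × 0.5; SINE × 0.4; terminal-tissue class multipliers LTR × 2.0,
SINE × 0.25, islands × 1.5 (embryonic × 1); skipped exons × 0.3 over the
exon ± 1 region. Per-gene latent factors `z ~ N(0,1)` couple element
methylation to expression via `exp(c·z)` with signed strengths c:
upstream −0.4, downstream −0.35, promoter −0.1, last exon +0.8; the
coupling is attenuated × 0.3 for genes with a promoter CpG island. The
strengths are exponents, not target correlations; recovery tests assert
sign and ordering.

**Peaks.** Each region seeds a peak event with probability
`peak_scale (0.15) × p`, and an event spans the seed ± 1 region (~300 bp,
the width scale of real peak calls). Seed draws share one uniform stream
across tissues plus a small tissue-specific jitter (10%), so same-class
tissues share most peak positions while class multipliers differentiate
embryonic from terminal tissues at repeat and island regions. Event regions
get probability 0.9; background is clipped to [0.01, 0.6], so thresholding
maximal runs at p ≥ 0.8 recovers exactly the planted events, and peak
density is proportional to the planted multipliers (~2.2 k peaks per tissue
on the 8 Mb default genome, comparable to real peak densities per Mb).

**Fragments.** Enriched fragments are placed with multinomial weights ∝ p,
flow-through ∝ 1 − p, midpoints uniform within the region, fixed 300 bp
length. **Expression** is drawn by a Gaussian copula against z
(ρ = 0.9) and multinomial counts over genes; **junctions** include every
adjacent-exon junction (support scaled to expression) plus exactly one
exon-skipping junction per registered skipped exon.

**What it does not emulate:** sequence content (no FASTA; CpG density,
mappability and GC bias are absent), read-level error, fragment-length
variance, biological replicates, and chromosome-scale heterogeneity.
Passing recovery tests therefore demonstrates that the pipeline's
statistics recover planted effects through realistic sampling noise — not
that real libraries are free of the biases the generator omits.

## Determinism and numerics

All randomness derives from explicit seeds through `numpy` `SeedSequence`
streams keyed by purpose (genome, noise, peak state, per-tissue jitter,
fragments, expression), so any artifact is reproducible from its seed
alone and tissues can be generated independently yet share their common
streams. Bootstrap shuffles spawn one child stream per shuffle. k-means
uses scikit-learn with a fixed `random_state`. The Baum–Welch convergence
tolerance (1e-6 log-likelihood units), emission floor (1e-6), Poisson
binarization p-value (1e-4), posterior threshold (0.5), and the 0.5
half-count are the package-wide numerical constants; peak centers of
even-length peaks use the floor midpoint as a deterministic tie-break, and
expression-decile ties break by gene id.

## Known limitations

* Within-exon profile shape is attenuated below fragment-length resolution
  (see scoring); on the default generator scale the cap-shape recovery is
  near the detection limit.
* The shuffle null is genome-uniform; GC- or chromosome-matched nulls are
  out of scope.
* Isoform-resolved gene models, UTR inference, intron retention and
  alternative 5′/3′ splice sites are out of scope; skipped-exon detection
  requires exact (or tolerance-bounded) junction/exon agreement.
* Cluster count k is a parameter, not selected by the package: no model
  selection over k is performed, and the default of 14 is a convention for
  multi-tissue methylation-state clustering rather than a data-driven
  optimum.
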