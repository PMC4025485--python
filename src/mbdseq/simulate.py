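"""Synthetic MBD-seq study generator with recorded ground truth.

Generates a miniature multi-tissue methylation study — genome layout, gene
annotation, CpG-island and repeat tracks, a planted per-100 bp methylation
probability map per tissue, enriched/flow-through fragment libraries, peak
calls, expression counts, and splice junctions — so that every pipeline
stage has a recovery test against known truth.

Planted structure
-----------------
The methylome is a per-region probability map

    p = base_rate x element multipliers x repeat/tissue multipliers x noise

with a promoter dip, a cap-shaped within-exon profile, a 5'->3' gradient
across the gene body, a last-exon boost, repeat-class signatures (LTR-rich,
SINE-poor), CpG-island enrichment with tissue-class contrasts
(embryonic vs terminal), hypomethylated skipped exons, and per-gene latent
factors that couple element methylation to expression with signed,
element-specific strengths.  The last exon is exempted from the gradient and
carries ``last_exon_boost x mean(gradient)`` instead, so its planted effect
size relative to interior exons is the configured boost and does not
compound with the gradient.

Regions additionally enter a "peak-forming" state with probability
``peak_scale x p``; peak-state regions get probability ``high_level`` (above
the peak-calling threshold) while background stays clipped below it.  Peak
density is therefore proportional to the planted multipliers, and the
peak-state draw shares one random stream across tissues (plus a small
tissue-specific jitter) so tissues of the same class share most peak
positions.  Enriched fragments are placed with weight proportional to p,
flow-through fragments with weight proportional to 1 - p.
"""

from __future__ import annotations

import bisect
import json
import logging
import math
from collections.abc import Mapping
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .annotation import GeneModel, build_gene_model, write_gtf
from .intervals import GenomeLayout, GenomicInterval, MergedIndex
from .scoring import FragmentSet, PeakSet
from .splicing import SpliceJunction, write_junctions_tsv

logger = logging.getLogger(__name__)

# seed-stream tags (SeedSequence entropy = (seed, tag[, tissue_index]))
_TAG_GENOME = 0
_TAG_LATENT = 1
_TAG_SKIPPED = 2
_TAG_NOISE = 3
_TAG_PEAKSTATE = 4
_TAG_TISSUE_JITTER = 10
_TAG_FRAGMENTS = 11
_TAG_EXPRESSION = 12


def _rng(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed),) + tags))


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generator (defaults are the
    desk-scale study; see the methods note for rationale)."""

    seed: int
    n_chroms: int = 4
    chrom_length: int = 2_000_000
    n_genes: int = 300
    exons_per_gene: tuple[int, int] = (2, 10)
    exon_length: tuple[int, int] = (150, 400)
    intron_length: tuple[int, int] = (200, 2000)
    utr_length: tuple[int, int] = (40, 120)
    gene_gap: tuple[int, int] = (4000, 28000)

    cpg_island_fraction: float = 0.5
    cpg_island_length: tuple[int, int] = (200, 800)
    n_intergenic_islands: int = 80
    n_line: int = 1200
    n_sine: int = 2000
    n_ltr: int = 900
    repeat_length: tuple[int, int] = (150, 600)

    region_size: int = 100
    base_rate: float = 0.15
    promoter_dip: float = 0.25
    last_exon_boost: float = 2.0
    exon_shape_amp: float = 0.6
    gradient_5to3: float = 1.6
    ltr_boost: float = 3.0
    sine_suppression: float = 0.4
    line_suppression: float = 0.5
    cpg_island_boost: float = 5.0
    noise_sigma: float = 0.25

    tissues: dict[str, str] = field(
        default_factory=lambda: {
            "onecell": "embryonic",
            "mbt": "embryonic",
            "brain": "terminal",
            "liver": "terminal",
        }
    )
    class_multipliers: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "embryonic": {"LTR": 1.0, "SINE": 1.0, "cpg_island": 1.0},
            "terminal": {"LTR": 2.0, "SINE": 0.25, "cpg_island": 1.5},
        }
    )

    expression_corr: dict[str, float] = field(
        default_factory=lambda: {
            "upstream_10kb": -0.4,
            "downstream_10kb": -0.35,
            "promoter": -0.1,
            "last_exon": 0.8,
        }
    )
    cpg_promoter_attenuation: float = 0.3
    expression_copula_rho: float = 0.9
    expression_library_size: int = 500_000

    skipped_fraction: float = 0.3
    skipped_multiplier: float = 0.3

    peak_scale: float = 0.15
    peak_prob_cap: float = 0.95
    background_cap: float = 0.6
    high_level: float = 0.9
    peak_threshold: float = 0.8
    tissue_jitter: float = 0.1

    depth_enriched: int = 200_000
    depth_unenriched: int = 200_000
    fragment_length: int = 300
    peak_event_halfwidth: int = 1  # regions a peak event extends past its seed

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0 < self.high_level <= 1 or self.peak_threshold > self.high_level:
            raise ValueError("need peak_threshold <= high_level <= 1")
        if self.background_cap >= self.peak_threshold:
            raise ValueError("background_cap must stay below peak_threshold")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides)
        for key in ("exons_per_gene", "exon_length", "intron_length", "utr_length",
                    "gene_gap", "cpg_island_length", "repeat_length"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RegionProbMap:
    """Planted methylation probability per fixed-size region."""

    layout: GenomeLayout
    region_size: int
    probs: dict[str, np.ndarray]

    def concat(self) -> np.ndarray:
        return np.concatenate([self.probs[c] for c in self.layout.chrom_names])

    @property
    def n_regions(self) -> int:
        return int(sum(len(v) for v in self.probs.values()))

    def region_intervals(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        n = len(self.probs[chrom])
        starts = np.arange(n, dtype=np.int64) * self.region_size
        ends = np.minimum(starts + self.region_size, self.layout.length_of(chrom))
        return starts, ends


@dataclass(frozen=True)
class SkippedExonTruth:
    gene_id: str
    skipped_exon: GenomicInterval
    upstream_exon: GenomicInterval  # genomic-left neighbor
    downstream_exon: GenomicInterval  # genomic-right neighbor


@dataclass
class SyntheticTruth:
    """Everything needed to score recovery without re-simulation."""

    tissue_classes: dict[str, str]
    gene_latent: dict[str, float]
    promoter_cpg_genes: set[str]
    skipped: list[SkippedExonTruth]
    prob_maps: dict[str, RegionProbMap]
    planted_states: dict[str, dict[str, np.ndarray]]


@dataclass
class TissueData:
    name: str
    tissue_class: str
    prob_map: RegionProbMap
    peaks: PeakSet
    enriched: FragmentSet
    unenriched: FragmentSet
    counts: pd.DataFrame
    junctions: list[SpliceJunction]


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    layout: GenomeLayout
    genes: list[GeneModel]
    feature_tracks: dict[str, list[GenomicInterval]]
    tissues: dict[str, TissueData]
    truth: SyntheticTruth


class _Occupancy:
    """Per-chromosome sorted non-overlapping interval store for rejection
    sampling of feature placements."""

    def __init__(self) -> None:
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}

    def conflicts(self, chrom: str, start: int, end: int) -> bool:
        starts = self._starts.get(chrom)
        if not starts:
            return False
        ends = self._ends[chrom]
        i = bisect.bisect_right(starts, start)
        if i > 0 and ends[i - 1] > start:
            return True
        return i < len(starts) and starts[i] < end

    def add(self, chrom: str, start: int, end: int) -> None:
        starts = self._starts.setdefault(chrom, [])
        ends = self._ends.setdefault(chrom, [])
        i = bisect.bisect_right(starts, start)
        starts.insert(i, start)
        ends.insert(i, end)


def _rand_int(rng: np.random.Generator, bounds: tuple[int, int]) -> int:
    return int(rng.integers(bounds[0], bounds[1] + 1))


def simulate_genome(
    config: SimulationConfig,
) -> tuple[GenomeLayout, list[GeneModel], dict[str, list[GenomicInterval]], set[str]]:
    """Non-overlapping gene models plus CpG-island and repeat tracks.

    Returns (layout, genes, feature tracks, gene ids whose promoter carries a
    CpG island).  Deterministic under the config seed.
    """
    rng = _rng(config.seed, _TAG_GENOME)
    layout = GenomeLayout(
        {f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)}
    )
    chroms = list(layout.chrom_names)
    genes: list[GeneModel] = []
    ci = 0
    cursor = _rand_int(rng, config.gene_gap)
    while len(genes) < config.n_genes and ci < len(chroms):
        n_ex = _rand_int(rng, config.exons_per_gene)
        exon_lens = [_rand_int(rng, config.exon_length) for _ in range(n_ex)]
        intron_lens = [_rand_int(rng, config.intron_length) for _ in range(n_ex - 1)]
        strand = "+" if rng.random() < 0.5 else "-"
        length = sum(exon_lens) + sum(intron_lens)
        if cursor + length + 2000 > config.chrom_length:
            ci += 1
            cursor = _rand_int(rng, config.gene_gap)
            continue
        chrom = chroms[ci]
        exons = []
        pos = cursor
        for el, il in zip(exon_lens, intron_lens + [0]):
            exons.append(GenomicInterval(chrom, pos, pos + el, strand))
            pos += el + il
        # UTRs live at the oriented ends of the terminal exons
        five_exon = exons[0] if strand == "+" else exons[-1]
        three_exon = exons[-1] if strand == "+" else exons[0]
        u5 = min(_rand_int(rng, config.utr_length), five_exon.length - 20)
        u3 = min(_rand_int(rng, config.utr_length), three_exon.length - 20)
        if strand == "+":
            utr5 = [GenomicInterval(chrom, five_exon.start, five_exon.start + u5, strand)]
            utr3 = [GenomicInterval(chrom, three_exon.end - u3, three_exon.end, strand)]
        else:
            utr5 = [GenomicInterval(chrom, five_exon.end - u5, five_exon.end, strand)]
            utr3 = [GenomicInterval(chrom, three_exon.start, three_exon.start + u3, strand)]
        gene_id = f"g{len(genes) + 1:04d}"
        genes.append(build_gene_model(gene_id, chrom, strand, exons, utr5, utr3))
        cursor = pos + _rand_int(rng, config.gene_gap)
    if len(genes) < config.n_genes:
        logger.warning(
            "placed only %d of %d genes before running out of genome",
            len(genes),
            config.n_genes,
        )

    occupancy = _Occupancy()
    islands: list[GenomicInterval] = []
    promoter_cpg: set[str] = set()
    for gene in genes:
        if rng.random() >= config.cpg_island_fraction:
            continue
        size = _rand_int(rng, config.cpg_island_length)
        iv = layout.clip(gene.chrom, gene.tss - size // 2, gene.tss - size // 2 + size)
        if iv is None:
            continue
        islands.append(iv)
        occupancy.add(iv.chrom, iv.start, iv.end)
        promoter_cpg.add(gene.gene_id)

    padded_genes = MergedIndex(
        [
            layout.clip(g.chrom, g.interval.start - 2500, g.interval.end + 2500)
            for g in genes
        ]
    )

    def place(n: int, bounds: tuple[int, int]) -> list[GenomicInterval]:
        placed = []
        tries = 0
        while len(placed) < n and tries < 50 * n:
            tries += 1
            size = _rand_int(rng, bounds)
            chrom = chroms[int(rng.integers(len(chroms)))]
            start = int(rng.integers(0, config.chrom_length - size))
            if occupancy.conflicts(chrom, start, start + size):
                continue
            if padded_genes.overlaps_any(
                chrom, np.asarray([start]), np.asarray([start + size])
            )[0]:
                continue
            iv = GenomicInterval(chrom, start, start + size)
            placed.append(iv)
            occupancy.add(chrom, start, start + size)
        if len(placed) < n:
            logger.warning("placed only %d of %d features", len(placed), n)
        return placed

    tracks = {
        "cpg_island": islands + place(config.n_intergenic_islands, config.cpg_island_length),
        "LINE": place(config.n_line, config.repeat_length),
        "SINE": place(config.n_sine, config.repeat_length),
        "LTR": place(config.n_ltr, config.repeat_length),
    }
    return layout, genes, tracks, promoter_cpg


def _region_slice(start: int, end: int, rs: int, n_regions: int) -> slice:
    """Regions whose midpoint falls inside [start, end)."""
    half = rs // 2
    r0 = max(0, -((half - start) // rs))  # ceil((start - half) / rs)
    r1 = max(0, -((half - end) // rs))
    return slice(min(r0, n_regions), min(r1, n_regions))


def _exon_cap(t: np.ndarray, amp: float) -> np.ndarray:
    """Cap-shaped within-exon multiplier with unit mean: low edges, high
    center (1 - amp at the edges, 1 + amp/2 at the center)."""
    return 1.0 + amp * (6.0 * t * (1.0 - t) - 1.0)


def _build_shared_multipliers(
    config: SimulationConfig,
    layout: GenomeLayout,
    genes: list[GeneModel],
    tracks: Mapping[str, list[GenomicInterval]],
    promoter_cpg: set[str],
    gene_latent: Mapping[str, float],
    skipped: list[SkippedExonTruth],
) -> tuple[dict[str, np.ndarray], dict[str, dict[str, np.ndarray]]]:
    """Relative (base-rate-free, noise-free) multiplier map shared by all
    tissues, plus boolean region masks for the class-contrast tracks."""
    rs = config.region_size
    mult = {
        chrom: np.ones(math.ceil(length / rs))
        for chrom, length in layout.chrom_lengths.items()
    }
    grad = config.gradient_5to3

    for gene in genes:
        arr = mult[gene.chrom]
        n = len(arr)
        gs, ge = gene.interval.start, gene.interval.end
        body = _region_slice(gs, ge, rs, n)
        mids = np.arange(body.start, body.stop) * rs + rs // 2
        t = (mids - gs) / max(ge - gs, 1)
        if gene.strand == "-":
            t = 1.0 - t
        arr[body] *= 1.0 + (grad - 1.0) * t

        for i, exon in enumerate(gene.exons):
            sl = _region_slice(exon.start, exon.end, rs, n)
            if sl.start >= sl.stop:
                continue
            e_mids = np.arange(sl.start, sl.stop) * rs + rs // 2
            te = (e_mids - exon.start) / exon.length
            if gene.strand == "-":
                te = 1.0 - te
            arr[sl] *= _exon_cap(te, config.exon_shape_amp)
        if gene.n_exons > 1:
            # last exon: the boost replaces the gradient and, like the
            # skipped-exon effect, extends one region past the exon
            # boundaries (fragment-resolution blur; see module docstring)
            last = gene.exons[-1]
            sl = _region_slice(last.start - rs, last.end + rs, rs, n)
            if sl.start < sl.stop:
                e_mids = np.arange(sl.start, sl.stop) * rs + rs // 2
                t_here = np.clip((e_mids - gs) / max(ge - gs, 1), 0.0, 1.0)
                if gene.strand == "-":
                    t_here = 1.0 - t_here
                g_here = 1.0 + (grad - 1.0) * t_here
                arr[sl] *= config.last_exon_boost * (1.0 + grad) / 2.0 / g_here

        z = gene_latent[gene.gene_id]
        atten = (
            config.cpg_promoter_attenuation
            if gene.gene_id in promoter_cpg
            else 1.0
        )
        if gene.strand == "+":
            prom = (gs - 2000, gs)
            up = (gs - 12000, gs - 2000)
            down = (ge, ge + 10000)
        else:
            prom = (ge, ge + 2000)
            up = (ge + 2000, ge + 12000)
            down = (gs - 10000, gs)
        coupled = {
            "promoter": prom,
            "upstream_10kb": up,
            "downstream_10kb": down,
            "last_exon": (gene.exons[-1].start, gene.exons[-1].end),
        }
        arr[_region_slice(*prom, rs, n)] *= config.promoter_dip
        for cls, (a, b) in coupled.items():
            c = config.expression_corr.get(cls, 0.0) * atten
            if c:
                arr[_region_slice(max(a, 0), max(b, 0), rs, n)] *= math.exp(c * z)

    for entry in skipped:
        arr = mult[entry.skipped_exon.chrom]
        sl = _region_slice(
            entry.skipped_exon.start - rs,
            entry.skipped_exon.end + rs,
            rs,
            len(arr),
        )
        arr[sl] *= config.skipped_multiplier

    masks: dict[str, dict[str, np.ndarray]] = {}
    base_mult = {
        "cpg_island": config.cpg_island_boost,
        "LINE": config.line_suppression,
        "SINE": config.sine_suppression,
        "LTR": config.ltr_boost,
    }
    for name, track in tracks.items():
        masks[name] = {
            chrom: np.zeros(len(arr), dtype=bool) for chrom, arr in mult.items()
        }
        for iv in track:
            sl = _region_slice(iv.start, iv.end, rs, len(mult[iv.chrom]))
            masks[name][iv.chrom][sl] = True
        for chrom in mult:
            mult[chrom] = np.where(
                masks[name][chrom], mult[chrom] * base_mult[name], mult[chrom]
            )
    return mult, masks


def simulate_methylome(
    config: SimulationConfig,
    layout: GenomeLayout,
    shared_mult: Mapping[str, np.ndarray],
    masks: Mapping[str, Mapping[str, np.ndarray]],
    noise: Mapping[str, np.ndarray],
    peak_uniform: Mapping[str, np.ndarray],
    tissue: str,
    tissue_index: int,
) -> tuple[RegionProbMap, dict[str, np.ndarray]]:
    """Per-tissue probability map and planted peak-state regions."""
    tissue_class = config.tissues[tissue]
    class_mult = config.class_multipliers.get(tissue_class, {})
    rng = _rng(config.seed, _TAG_TISSUE_JITTER, tissue_index)
    probs: dict[str, np.ndarray] = {}
    states: dict[str, np.ndarray] = {}
    for chrom in layout.chrom_names:
        m = shared_mult[chrom].copy()
        for name, factor in class_mult.items():
            if name in masks:
                m = np.where(masks[name][chrom], m * factor, m)
        m = config.base_rate * m * noise[chrom]
        q = np.clip(config.peak_scale * m, 0.0, config.peak_prob_cap)
        v = rng.random(len(m))
        seeded = (peak_uniform[chrom] < q) | (v < config.tissue_jitter * q)
        # a peak event spans the seed region +/- halfwidth (MACS2-scale widths)
        state = seeded.copy()
        for shift in range(1, config.peak_event_halfwidth + 1):
            state[shift:] |= seeded[:-shift]
            state[:-shift] |= seeded[shift:]
        probs[chrom] = np.where(
            state, config.high_level, np.clip(m, 0.01, config.background_cap)
        )
        states[chrom] = state.astype(np.uint8)
    return RegionProbMap(layout, config.region_size, probs), states


def simulate_fragments(
    prob_map: RegionProbMap,
    depth_enriched: int,
    depth_unenriched: int,
    fragment_length: int = 300,
    rng: np.random.Generator | int = 0,
) -> tuple[FragmentSet, FragmentSet]:
    """Fragment libraries: enriched sampling weight proportional to the local
    methylation probability, flow-through proportional to its complement."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    layout = prob_map.layout
    p = prob_map.concat()
    chrom_sizes = [len(prob_map.probs[c]) for c in layout.chrom_names]
    offsets = np.cumsum([0] + chrom_sizes)
    out = []
    for depth, weights, label in (
        (depth_enriched, p, "enriched"),
        (depth_unenriched, 1.0 - p, "unenriched"),
    ):
        counts = rng.multinomial(depth, weights / weights.sum())
        arrays: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for i, chrom in enumerate(layout.chrom_names):
            local = counts[offsets[i] : offsets[i + 1]]
            regions = np.repeat(np.arange(len(local)), local)
            mids = regions * prob_map.region_size + rng.integers(
                0, prob_map.region_size, size=len(regions)
            )
            starts = np.clip(
                mids - fragment_length // 2,
                0,
                layout.length_of(chrom) - fragment_length,
            )
            arrays[chrom] = (starts, starts + fragment_length)
        out.append(FragmentSet(label, arrays, total_count=depth))
    return out[0], out[1]


def simulate_peaks(prob_map: RegionProbMap, threshold: float = 0.8) -> PeakSet:
    """Maximal runs of regions at or above ``threshold`` become peaks."""
    peaks = []
    rs = prob_map.region_size
    for chrom in prob_map.layout.chrom_names:
        mask = prob_map.probs[chrom] >= threshold
        if not mask.any():
            continue
        edges = np.diff(mask.astype(np.int8))
        starts = np.flatnonzero(edges == 1) + 1
        ends = np.flatnonzero(edges == -1) + 1
        if mask[0]:
            starts = np.r_[0, starts]
        if mask[-1]:
            ends = np.r_[ends, len(mask)]
        limit = prob_map.layout.length_of(chrom)
        for s, e in zip(starts, ends):
            peaks.append(GenomicInterval(chrom, int(s * rs), min(int(e * rs), limit)))
    return PeakSet(peaks, expanded=False)


def gaussian_copula(
    z: np.ndarray, rho: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw x with Pearson correlation ``rho`` to z on the latent normal
    scale (Spearman correlation (6/pi) asin(rho/2) after any monotone
    transform)."""
    eps = rng.standard_normal(len(z))
    return rho * z + math.sqrt(1.0 - rho**2) * eps


def simulate_expression_and_junctions(
    config: SimulationConfig,
    genes: list[GeneModel],
    gene_latent: Mapping[str, float],
    skipped: list[SkippedExonTruth],
    tissue_index: int,
) -> tuple[pd.DataFrame, list[SpliceJunction]]:
    """Per-gene counts rank-coupled to the planted latent factor, plus
    adjacent-exon junctions for every intron and one exon-skipping junction
    per registered skipped exon."""
    rng = _rng(config.seed, _TAG_EXPRESSION, tissue_index)
    z = np.asarray([gene_latent[g.gene_id] for g in genes])
    x = gaussian_copula(z, config.expression_copula_rho, rng)
    exonic_kb = np.asarray([sum(e.length for e in g.exons) / 1000 for g in genes])
    weights = np.exp(1.5 * x) * exonic_kb
    counts = rng.multinomial(config.expression_library_size, weights / weights.sum())
    table = pd.DataFrame(
        {"gene_id": [g.gene_id for g in genes], "count": counts.astype(int)}
    )
    count_of = dict(zip(table["gene_id"], table["count"]))
    skipped_by_gene = {s.gene_id: s for s in skipped}
    junctions: list[SpliceJunction] = []
    for gene in genes:
        support_scale = max(count_of[gene.gene_id], 1)
        exons = gene.exons_genomic
        for a, b in zip(exons, exons[1:]):
            junctions.append(
                SpliceJunction(
                    gene.chrom,
                    a.end,
                    b.start,
                    gene.strand,
                    1 + int(rng.poisson(support_scale / 100)),
                )
            )
        entry = skipped_by_gene.get(gene.gene_id)
        if entry is not None:
            junctions.append(
                SpliceJunction(
                    gene.chrom,
                    entry.upstream_exon.end,
                    entry.downstream_exon.start,
                    gene.strand,
                    1 + int(rng.poisson(support_scale / 200)),
                )
            )
    return table, junctions


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Run the full generator: genome, truth, and per-tissue data."""
    layout, genes, tracks, promoter_cpg = simulate_genome(config)

    latent_rng = _rng(config.seed, _TAG_LATENT)
    gene_latent = {
        g.gene_id: float(latent_rng.standard_normal()) for g in genes
    }

    skip_rng = _rng(config.seed, _TAG_SKIPPED)
    skipped: list[SkippedExonTruth] = []
    for gene in genes:
        if gene.n_exons < 3 or skip_rng.random() >= config.skipped_fraction:
            continue
        exons = gene.exons_genomic
        k = int(skip_rng.integers(1, len(exons) - 1))  # genomic-interior exon
        skipped.append(
            SkippedExonTruth(gene.gene_id, exons[k], exons[k - 1], exons[k + 1])
        )

    shared_mult, masks = _build_shared_multipliers(
        config, layout, genes, tracks, promoter_cpg, gene_latent, skipped
    )
    noise_rng = _rng(config.seed, _TAG_NOISE)
    peak_rng = _rng(config.seed, _TAG_PEAKSTATE)
    noise = {
        chrom: np.exp(config.noise_sigma * noise_rng.standard_normal(len(arr)))
        for chrom, arr in shared_mult.items()
    }
    peak_uniform = {
        chrom: peak_rng.random(len(arr)) for chrom, arr in shared_mult.items()
    }

    tissues: dict[str, TissueData] = {}
    prob_maps: dict[str, RegionProbMap] = {}
    planted_states: dict[str, dict[str, np.ndarray]] = {}
    for ti, (tissue, tissue_class) in enumerate(config.tissues.items()):
        prob_map, states = simulate_methylome(
            config, layout, shared_mult, masks, noise, peak_uniform, tissue, ti
        )
        enriched, unenriched = simulate_fragments(
            prob_map,
            config.depth_enriched,
            config.depth_unenriched,
            config.fragment_length,
            _rng(config.seed, _TAG_FRAGMENTS, ti),
        )
        peaks = simulate_peaks(prob_map, config.peak_threshold)
        counts, junctions = simulate_expression_and_junctions(
            config, genes, gene_latent, skipped, ti
        )
        prob_maps[tissue] = prob_map
        planted_states[tissue] = states
        tissues[tissue] = TissueData(
            name=tissue,
            tissue_class=tissue_class,
            prob_map=prob_map,
            peaks=peaks,
            enriched=enriched,
            unenriched=unenriched,
            counts=counts,
            junctions=junctions,
        )
    truth = SyntheticTruth(
        tissue_classes=dict(config.tissues),
        gene_latent=gene_latent,
        promoter_cpg_genes=promoter_cpg,
        skipped=skipped,
        prob_maps=prob_maps,
        planted_states=planted_states,
    )
    return SyntheticDataset(config, layout, genes, tracks, tissues, truth)


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> list[Path]:
    """Emit the dataset as standard text files (chrom.sizes, GTF, BED, TSV)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def record(path: Path) -> Path:
        written.append(path)
        return path

    mio.write_chrom_sizes(dataset.layout, record(outdir / "chrom.sizes"))
    write_gtf(dataset.genes, record(outdir / "genes.gtf"))
    for name, track in dataset.feature_tracks.items():
        mio.write_bed(track, record(outdir / f"{name}.bed"))
    for tissue, data in dataset.tissues.items():
        tdir = outdir / tissue
        tdir.mkdir(exist_ok=True)
        data.enriched.to_bed(record(tdir / "enriched.bed"))
        data.unenriched.to_bed(record(tdir / "unenriched.bed"))
        data.peaks.to_bed(record(tdir / "peaks.bed"))
        data.counts.to_csv(record(tdir / "counts.tsv"), sep="\t", index=False)
        write_junctions_tsv(data.junctions, record(tdir / "junctions.tsv"))
    truth = {
        "tissue_classes": dataset.truth.tissue_classes,
        "promoter_cpg_genes": sorted(dataset.truth.promoter_cpg_genes),
        "gene_latent": dataset.truth.gene_latent,
        "skipped": [
            {
                "gene_id": s.gene_id,
                "chrom": s.skipped_exon.chrom,
                "start": s.skipped_exon.start,
                "end": s.skipped_exon.end,
            }
            for s in dataset.truth.skipped
        ],
    }
    record(outdir / "truth.json").write_text(json.dumps(truth, indent=1))
    return written
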