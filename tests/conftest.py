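"""Shared fixtures: the default synthetic study (session-scoped, since the
generator defaults define the study conditions every recovery test probes)
plus small helpers."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mbdseq.annotation import build_metagene_elements, elements_by_class
from mbdseq.intervals import GenomeLayout, GenomicInterval
from mbdseq.scoring import fragment_counts_fixed_windows
from mbdseq.segmentation import binarize, fit_two_state_hmm, posterior_decode, stack_posteriors
from mbdseq.simulate import SimulationConfig, simulate_dataset

settings.register_profile(
    "suite", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")

SEED = 20140321


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=SEED)


@pytest.fixture(scope="session")
def dataset(default_config):
    return simulate_dataset(default_config)


@pytest.fixture(scope="session")
def elements(dataset):
    return build_metagene_elements(dataset.genes, dataset.layout)


@pytest.fixture(scope="session")
def elements_map(elements):
    return elements_by_class(elements)


@pytest.fixture(scope="session")
def posteriors(dataset):
    """Per-tissue smoothed methylation posteriors on the 200 bp grid."""
    posts = {}
    for tissue, td in dataset.tissues.items():
        counts = fragment_counts_fixed_windows(td.enriched, dataset.layout, 200)
        track = binarize(counts, dataset.layout, 200, tissue=tissue)
        model = fit_two_state_hmm(track, seed=0)
        posts[tissue] = posterior_decode(model, track)
    return stack_posteriors(posts, dataset.layout, 200)


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)


@pytest.fixture()
def toy_layout():
    return GenomeLayout({"chr1": 1_000_000, "chr2": 600_000})


def random_intervals(rng, n, layout, max_len=500) -> list[GenomicInterval]:
    """Uniform random intervals for oracle comparisons."""
    out = []
    chroms = list(layout.chrom_names)
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        length = int(rng.integers(1, max_len))
        start = int(rng.integers(0, layout.length_of(chrom) - length))
        out.append(GenomicInterval(chrom, start, start + length))
    return out
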