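"""Shared fixtures: toy genomes and a small synthetic bundle.

Everything is generated programmatically; no data files ship with the tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from chipregions.annotation import GeneModel, partition_genome
from chipregions.classify import IntergenicClass
from chipregions.enrichment import CoverageTrack
from chipregions.simulate import SimulationConfig, simulate_bundle

SMALL_CLASS_COUNTS = {
    IntergenicClass.PROMOTER_SINGLE.value: 2,
    IntergenicClass.TERMINATOR_SINGLE.value: 2,
    IntergenicClass.BIDIRECTIONAL_PROMOTER.value: 1,
    IntergenicClass.SHARED_TERMINATOR.value: 1,
    IntergenicClass.PROMOTER_TERMINATOR_OVERLAP.value: 1,
}


def small_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A fast, small-genome configuration for unit tests (~0.1 Mb)."""
    kwargs = dict(
        seed=seed,
        n_genes=40,
        edge_margin=60_000,
        n_occupied_genes=8,
        planted_class_counts=dict(SMALL_CLASS_COUNTS),
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@pytest.fixture(scope="session")
def small_bundle():
    return simulate_bundle(small_config(seed=11))


@pytest.fixture
def two_gene_chrom():
    """chrom length 2000 with genes [100,500)+ and [900,1300)+."""
    genes = [
        GeneModel("gA", "chr1", 100, 500, "+"),
        GeneModel("gB", "chr1", 900, 1300, "+"),
    ]
    sizes = {"chr1": 2000}
    genic, intergenic = partition_genome(genes, sizes)
    return genes, sizes, genic, intergenic


def uniform_track(depth: float, sizes: dict[str, int]) -> CoverageTrack:
    return CoverageTrack({c: np.full(s, float(depth)) for c, s in sizes.items()}, sizes)
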