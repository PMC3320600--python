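from __future__ import annotations

import numpy as np
import pytest

from gencluster import GeneList, GeneRecord, GenomeAnnotation, SimConfig
from gencluster.synthetic import simulate_genome


@pytest.fixture
def toy_annotation() -> GenomeAnnotation:
    """Four genes: three spaced 9,499 bp apart on chr2L, one on chr3R."""
    return GenomeAnnotation([
        GeneRecord("A", "chr2L", 1000, 3000, "+"),
        GeneRecord("B", "chr2L", 12500, 14000, "-"),
        GeneRecord("C", "chr2L", 23500, 24000, "+"),
        GeneRecord("D", "chr3R", 5000, 6000, "+"),
    ])


@pytest.fixture
def toy_list() -> GeneList:
    return GeneList("toy", "all", ("A", "B", "C", "D"))


@pytest.fixture(scope="session")
def small_genome() -> GenomeAnnotation:
    """A 2 x 400-gene genome with fly-like spacing, for randomized checks."""
    return simulate_genome(SimConfig(n_chrom=2, genes_per_chrom=400, seed=101))


@pytest.fixture(scope="session")
def benchmark_genome() -> GenomeAnnotation:
    """The default-scale genome (5 x 2,000 genes) used by null-calibration
    and planted-recovery checks."""
    return simulate_genome(SimConfig(seed=202))


def random_sublist(ann: GenomeAnnotation, size: int,
                   rng: np.random.Generator, name: str = "rand") -> GeneList:
    ids = rng.choice(np.array(ann.ids, dtype=object), size=size, replace=False)
    return GeneList(name, "all", tuple(ids))
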