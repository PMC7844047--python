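from __future__ import annotations

import numpy as np
import pytest

from cggcat.genotype_io import CallSet, GenotypeCall
from cggcat.repeat_catalog import AlignParams, DetectionParams, canonical_motif_frames
from cggcat.synth_data import (
    PlantedLocus,
    SimulationConfig,
    generate_genome,
    plant_random_loci,
    simulate_population,
)


@pytest.fixture(scope="session")
def detection_params() -> DetectionParams:
    return DetectionParams()


@pytest.fixture(scope="session")
def align_params() -> AlignParams:
    return AlignParams()


@pytest.fixture(scope="session")
def cgg_class():
    return canonical_motif_frames("CGG")


@pytest.fixture(scope="session")
def small_genome_bundle():
    """A 10-kb genome with three planted pure repeats, plus its truth table."""
    config = SimulationConfig(
        seed=3,
        genome_length=10_000,
        planted_loci=[
            PlantedLocus("chr1", 1_000, "CGG", 7),
            PlantedLocus("chr1", 3_000, "GCC", 5),
            PlantedLocus("chr1", 6_000, "CGC", 12),
        ],
    )
    genome, truth = generate_genome(config)
    return config, genome, truth


@pytest.fixture(scope="session")
def cohort_bundle():
    """A 150-kb genome, 20 loci, 10-sample cohort with gene-model-compatible
    spacing; shared by genotype/popstats/pipeline tests."""
    rng = np.random.default_rng(7)
    planted = plant_random_loci(rng, 20, 150_000, min_spacing=2_700)
    config = SimulationConfig(
        seed=7, genome_length=150_000, planted_loci=planted, n_samples=10
    )
    genome, truth = generate_genome(config)
    table = simulate_population(truth, config)
    return config, genome, truth, table


def make_callset(rows: dict[tuple[str, str], tuple[int, int] | None]) -> CallSet:
    """Build a CallSet from {(sample, locus): allele pair or None} rows."""
    samples = sorted({s for s, _ in rows})
    loci = sorted({l for _, l in rows})
    calls = {
        (s, l): GenotypeCall(s, l, units) for (s, l), units in rows.items()
    }
    return CallSet(samples=samples, loci=loci, calls=calls)
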