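import numpy as np
import pytest

from rnasnv.formats_io import ObservationStore, ReferenceGenome
from rnasnv.genotyper import PriorConfig, call_variants_from_store
from rnasnv.simulate import (
    SimulationConfig,
    plant_variants,
    sample_reads,
    simulate_genome_and_transcripts,
)


@pytest.fixture(scope="session")
def tiny_dataset():
    """A small but complete simulated experiment shared across test modules."""
    config = SimulationConfig(
        seed=11,
        genome_length=120_000,
        n_transcripts=20,
        heterozygosity_rate=0.01,
        reads_per_lane=3_000,
        n_lanes=4,
        quality_5prime=30,
        quality_3prime=30,
        expression_sigma=0.8,
    )
    genome, models = simulate_genome_and_transcripts(config)
    truth = plant_variants(genome, models, config)
    sample = sample_reads(genome, models, truth, config)
    return {
        "config": config,
        "genome": genome,
        "models": models,
        "truth": truth,
        "sample": sample,
        "reference": ReferenceGenome(genome),
    }


@pytest.fixture(scope="session")
def recovery_dataset():
    """Even-coverage, calibrated-quality dataset with ~1000 planted variants.

    Constant q=30 qualities, uniform expression, ~44x mean coverage over
    ~100 kb of exonic sequence; used for the end-to-end parameter-recovery
    checks.
    """
    config = SimulationConfig(
        seed=20090,
        genome_length=650_000,
        n_transcripts=100,
        heterozygosity_rate=0.01,
        reads_per_lane=20_000,
        n_lanes=7,
        quality_5prime=30,
        quality_3prime=30,
        expression_sigma=0.0,
    )
    genome, models = simulate_genome_and_transcripts(config)
    truth = plant_variants(genome, models, config)
    sample = sample_reads(genome, models, truth, config)
    reference = ReferenceGenome(genome)
    store = ObservationStore.from_reads(sample.genomic_reads)
    calls = call_variants_from_store(
        store, reference, PriorConfig(0.001), emit_reference_calls=True
    )
    return {
        "config": config,
        "genome": genome,
        "models": models,
        "truth": truth.individual(0),
        "sample": sample,
        "reference": reference,
        "store": store,
        "calls": calls,
    }
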