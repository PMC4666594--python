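import numpy as np
import pytest

from genomogram.sequences import (
    GeneProfile,
    SimulationConfig,
    simulate_dataset,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_config() -> SimulationConfig:
    """A scaled-down generator config: three genes, four classes."""
    genes = [
        GeneProfile("geneA", 400, (0.35, 0.15, 0.15, 0.35)),
        GeneProfile("geneB", 600, (0.25, 0.25, 0.25, 0.25)),
        GeneProfile("geneC", 500, (0.15, 0.35, 0.35, 0.15)),
    ]
    counts = {
        "Normal": 12,
        "geneA Substitution": 10,
        "geneB Deletion": 10,
        "geneC Substitution": 10,
    }
    return SimulationConfig(genes=genes, class_counts=counts,
                            deletion_length_range=(1, 10))


@pytest.fixture
def small_dataset():
    return simulate_dataset(small_config(), seed=7)
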