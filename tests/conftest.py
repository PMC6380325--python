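import numpy as np
import pytest

from phsdup.simulate import SimulationConfig


@pytest.fixture
def small_config():
    """A fast scenario: 4 genomes, 120 kb, a handful of events."""
    return SimulationConfig(
        genome_length=120_000,
        n_genomes=4,
        n_events=12,
        mean_depth=30.0,
        divergence_rate=0.01,
        seed=11,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
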