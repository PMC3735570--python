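import numpy as np
import pytest

from rgene_atlas.synthetic_data import SimConfig, generate_genome


@pytest.fixture(scope="session")
def sim():
    """One seeded synthetic genome shared across the suite (default study
    conditions: 60 genes, 5 clusters, 4 duplicate families, 30 markers)."""
    return generate_genome(SimConfig(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
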