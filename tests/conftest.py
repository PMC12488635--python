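import numpy as np
import pytest

from phagegate import FixtureSpec, ModelConfig
from phagegate.residue_tables import AMINO_ACIDS


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_protein(rng, length):
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


@pytest.fixture
def toy_model_config():
    """Small architecture that trains in well under a second on toy data."""
    return ModelConfig(channels=(8, 16), fc_width=16, epochs=30, seed=7)


@pytest.fixture
def fixture_spec():
    return FixtureSpec(n_hosts=10, n_phages=12, positive_fraction=0.3, seed=4)
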