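import numpy as np
import pytest

from esanet.backbone import ArchitectureSpec
from esanet.data import SyntheticDatasetSpec, synthetic_dataset
from esanet.training import set_global_seed


@pytest.fixture(autouse=True)
def _seed_everything():
    """Every test starts from the same global RNG state."""
    set_global_seed(2022)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_arch():
    """A desk-scale architecture spec (full surgery enabled)."""
    return ArchitectureSpec(stage_block_counts=(1, 1, 1, 1),
                            stage_widths=(8, 16, 32, 64),
                            num_classes=5, dropout_rate=0.1)


@pytest.fixture(scope="session")
def synth_spec():
    return SyntheticDatasetSpec(num_classes=5, samples_per_class=40,
                                image_size=32, seed=2022)


@pytest.fixture(scope="session")
def synth_data(synth_spec):
    """The 5-class, 200-image seeded synthetic set used by the training tests."""
    return synthetic_dataset(synth_spec)
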