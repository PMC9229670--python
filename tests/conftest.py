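import numpy as np
import pytest

from vesselgan.networks import DiscriminatorConfig, GeneratorConfig
from vesselgan.phantom import PhantomConfig, phantom_dataset
from vesselgan.train import TrainConfig


@pytest.fixture(scope="session")
def tiny_phantom_cfg():
    """Desk-scale phantom: 16x16x4 slices, thin vessels."""
    return PhantomConfig(
        n_slices=4, height=16, width=16, n_vessels=2,
        radius_range=(1.0, 2.0), seed=11,
    )


@pytest.fixture(scope="session")
def tiny_volumes(tiny_phantom_cfg):
    return phantom_dataset(tiny_phantom_cfg, 4)


@pytest.fixture(scope="session")
def small_phantom_cfg():
    """The study-shaped phantom used for the training smoke runs."""
    return PhantomConfig(seed=7)  # 32 slices of 64x64, 3 vessels


@pytest.fixture
def tiny_net_cfgs():
    return (
        GeneratorConfig(base_filters=4, res_base_filters=4),
        DiscriminatorConfig(base_filters=4),
    )


@pytest.fixture
def tiny_train_cfg():
    return TrainConfig(epochs=2, batch_size=10, seed=3, early_stop_patience=None)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
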