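import numpy as np
import pytest

from polypseg.network import DLGRAFENet, NetworkConfig
from polypseg.synthetic import SyntheticSpec, generate_sample


@pytest.fixture(scope="session")
def small_spec():
    """Session-wide 64-pixel synthetic spec used by most image fixtures."""
    return SyntheticSpec(image_size=64, seed=0)


@pytest.fixture(scope="session")
def small_batch(small_spec):
    """Four 64x64 image/mask pairs as stacked arrays."""
    samples = [generate_sample(small_spec, i) for i in range(4)]
    images = np.stack([s.image for s in samples])
    masks = np.stack([s.mask for s in samples])
    return images, masks


@pytest.fixture(scope="session")
def tiny_config():
    """A narrow network configuration for fast structural tests."""
    return NetworkConfig(
        filters=(8, 8, 16, 16, 32),
        input_size=64,
        decoder_widths=(16, 16, 8, 8),
        efe_reduction=1,
        ssia_mid_channels=8,
        head_width=8,
    )


@pytest.fixture(scope="session")
def tiny_network(tiny_config):
    return DLGRAFENet(tiny_config, seed=0)
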