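import numpy as np
import pytest

from marcnet.artifact_sim import DatasetConfig, build_dataset
from marcnet.phantom import MetalMask, generate_metal_mask, generate_phantom


@pytest.fixture(scope="session")
def phantom64():
    return generate_phantom(1, (64, 64))


@pytest.fixture(scope="session")
def phantom128():
    return generate_phantom(2, (128, 128))


@pytest.fixture(scope="session")
def mask64():
    return generate_metal_mask(1, (64, 64), "ovoid-pair")


@pytest.fixture(scope="session")
def empty_mask64():
    return MetalMask(np.zeros((64, 64), dtype=bool))


@pytest.fixture(scope="session")
def tiny_dataset():
    """4 subjects x 2 slices of 64x64; small but split-complete."""
    return build_dataset(4, 2, seed=7, config=DatasetConfig(size=(64, 64)))


@pytest.fixture(scope="session")
def inscribed_circle128():
    yy, xx = np.mgrid[0:128, 0:128]
    return (yy - 63.5) ** 2 + (xx - 63.5) ** 2 <= 63.5**2
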