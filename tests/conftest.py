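import numpy as np
import pytest

from vibromap.core import HyperspectralImage, SpectralAxis


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_axis():
    return SpectralAxis(values=np.arange(950.0, 1014.0, 4.0), modality="ftir")


@pytest.fixture
def small_image(rng, small_axis):
    cube = rng.uniform(0.1, 1.0, size=(3, 4, len(small_axis)))
    return HyperspectralImage(axis=small_axis, cube=cube, metadata={"source": "fixture"})
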