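import numpy as np
import pytest

from ahht.synthetic import make_block_image


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def uniform_image():
    """A 16x16 image of a single mid-gray color."""
    return np.full((16, 16, 3), 128, dtype=np.uint8)


@pytest.fixture
def four_block_fixture():
    return make_block_image(k=4, size=(96, 128), noise_sigma=4.0, seed=7)


def random_label_map(rng, shape=(5, 5), n_labels=3):
    return rng.integers(0, n_labels, size=shape)
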