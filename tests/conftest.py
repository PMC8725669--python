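import numpy as np
import pytest

from sonoquant import IcaSaliencyExtractor, make_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantom_set():
    """Small labelled phantom cohort shared across tests."""
    return make_dataset(30, 15, seed=1, difficulty=0.3)


@pytest.fixture(scope="session")
def fitted_extractor(phantom_set):
    """ICA saliency model fitted on a training subset of the phantoms."""
    ex = IcaSaliencyExtractor(k=16, max_patches=8000, seed=0)
    ex.fit([s.image for s in phantom_set[:8]] + [s.image for s in phantom_set[-4:]])
    return ex
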