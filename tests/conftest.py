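import numpy as np
import pytest

from leukoseg import SmearParams, make_smear


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def default_smear():
    """One deterministic synthetic smear with its ground-truth mask."""
    return make_smear(SmearParams(seed=7))


def random_mask(rng, shape=(16, 16), p=0.5):
    return rng.random(shape) < p
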