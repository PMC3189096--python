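import numpy as np
import pytest

from menseg.histogram_fcm import ImagePair


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_pair(t1, t2) -> ImagePair:
    return ImagePair(t1=np.asarray(t1, dtype=np.uint8), t2=np.asarray(t2, dtype=np.uint8))


@pytest.fixture
def random_pair(rng):
    def _make(shape=(16, 16), low=0, high=256):
        return make_pair(
            rng.integers(low, high, shape),
            rng.integers(low, high, shape),
        )

    return _make
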