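import numpy as np
import pytest


@pytest.fixture
def rng():
    """Deterministic generator for test data."""
    return np.random.default_rng(20240901)


def random_int_image(rng, shape=(8, 8), high=20):
    """Integer-valued float image: window sums are exactly representable,
    so separable and brute-force means agree bit for bit."""
    return rng.integers(0, high, size=shape).astype(float)
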