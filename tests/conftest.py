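import numpy as np
import pytest
from hypothesis import settings

from landmarker.matrix import ExpressionMatrix

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_matrix(values, prefix_g="g", prefix_s="s"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values,
        [f"{prefix_g}{i}" for i in range(values.shape[0])],
        [f"{prefix_s}{j}" for j in range(values.shape[1])],
    )


@pytest.fixture
def small_matrix(rng):
    """20 genes × 12 samples of smooth random values in [4, 15]."""
    v = 4 + 11 * rng.random((20, 12))
    return make_matrix(v)
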