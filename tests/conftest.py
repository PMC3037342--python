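import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_matrix(rng):
    """A 6x5 matrix of plain Gaussian noise."""
    import corrbic as cb

    return cb.ExpressionMatrix.from_array(rng.normal(size=(6, 5)))
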