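import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_trace(rng, n: int, integer: bool = False) -> np.ndarray:
    """Random test trace; integer-valued traces exercise plateaus and ties."""
    if integer:
        return rng.integers(0, 6, size=n).astype(float)
    return rng.normal(0.0, 1.0, size=n).cumsum() + rng.normal(0.0, 0.3, size=n)
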