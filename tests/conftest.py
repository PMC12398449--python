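import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from casecrossover import generate, preset

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def delayed_series():
    """One deterministic synthetic series with a true RR 1.10 effect at lag 14."""
    series, truth = generate(preset("delayed", independent_exposure=True))
    return series, truth


@pytest.fixture(scope="session")
def small_series():
    """Two-year series for fast pipeline tests."""
    series, _ = generate(preset("acute", independent_exposure=True, n_days=730))
    return series


def per_replicate_seeds(base: int, n: int) -> np.ndarray:
    """Deterministic replicate seeds below 2**31, derived from one base seed."""
    return np.random.default_rng(base).integers(0, 2**31 - 1, size=n)
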