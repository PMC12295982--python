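import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_symmetric(rng, n, density=0.5, scale=1.0):
    """Random symmetric zero-diagonal nonnegative matrix."""
    m = rng.random((n, n)) * (rng.random((n, n)) < density) * scale
    m = np.triu(m, k=1)
    return m + m.T


@pytest.fixture
def tiny_spec():
    from rinse import SyntheticSpec

    return SyntheticSpec(n_residues=24, n_frames=12, n_hubs=3, seed=7)


@pytest.fixture
def tiny_ensemble(tiny_spec):
    from rinse import generate_ensemble

    return generate_ensemble(tiny_spec, label="WT")
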