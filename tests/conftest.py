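import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy_forward():
    """Small forward model (~56 dipoles) for unit-level pipeline tests."""
    from beamcoh import experiment

    return experiment.build_forward_model(spacing=0.034, seed=0, keep_fraction=0.6)


@pytest.fixture(scope="session")
def small_forward():
    """Mid-size forward model (~280 dipoles) for end-to-end toy tests."""
    from beamcoh import experiment

    return experiment.build_forward_model(spacing=0.02, seed=0)


def random_psd_csd(rng, n, rank=None):
    """Random Hermitian PSD matrix (full rank by default)."""
    rank = rank or n
    A = rng.standard_normal((n, rank)) + 1j * rng.standard_normal((n, rank))
    return A @ A.conj().T / rank
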