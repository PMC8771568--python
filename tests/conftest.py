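import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default", derandomize=True, max_examples=60,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture(scope="session")
def quick_protocol():
    """A short recording (2.5 min) for unit tests that don't need the full
    10-min session."""
    from pulsekit import AcquisitionProtocol
    return AcquisitionProtocol(n_frames=82, duration_min=2.5)


@pytest.fixture(scope="session")
def clean_movie():
    """Noise-free, jitter-free default-protocol movie with 6 contractions."""
    from pulsekit import VesselSimSpec, generate_vessel_movie
    spec = VesselSimSpec(seed=11)
    return spec, *generate_vessel_movie(spec)
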