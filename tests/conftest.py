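import pytest
from hypothesis import settings

from picopp import SyntheticConfig, bohai_fixture, generate_stations

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def june_records():
    """50 seeded shelf-sea stations from the June cruise statistics."""
    return bohai_fixture("June", n_stations=50, seed=11)


@pytest.fixture(scope="session")
def ocean_records():
    """171 seeded open-ocean stations with a known 1.7x estimated:measured bias."""
    return generate_stations(SyntheticConfig(n_stations=171, seed=7, bias=1.7))


@pytest.fixture(scope="session")
def noiseless_records():
    """Stations whose 14C value equals the model estimate exactly."""
    return generate_stations(
        SyntheticConfig(n_stations=40, seed=5, bias=1.0, noise_sigma=0.0)
    )
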