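import numpy as np
import pytest

from heatexposure import SyntheticScenario, generate_surface, generate_temperature_cube


@pytest.fixture(scope="session")
def surface():
    """Small coastal surface: urban rings, vegetation, 3 lake columns."""
    return generate_surface(20, 24, lake_cols=3)


@pytest.fixture(scope="session")
def quiet_scenario():
    """Noise-free scenario with no heatwave and no lake cooling."""
    return SyntheticScenario(
        n_days=4,
        hw_start_day=0,
        hw_end_day=0,
        hw_amplitude_rural=0.0,
        hw_amplitude_urban=0.0,
        lake_cooling_amplitude=0.0,
        noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def quiet_cube(surface, quiet_scenario):
    return generate_temperature_cube(surface, quiet_scenario)


@pytest.fixture()
def rng():
    return np.random.default_rng(20120704)
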