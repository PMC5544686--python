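import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from aeromarine.core_io import EUKARYOTE, PROKARYOTE, MeteoState

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def open_ocean_meteo():
    """Typical open-ocean sampling conditions."""
    return MeteoState(u10=7.0, T=298.15, RH=80.0, P=101325.0)


@pytest.fixture
def standard_conditions():
    """The standard-condition meteorology used for the global equilibrium
    sweep (25 degC, 80 % RH, 1025 hPa), parameterised by wind speed."""
    return lambda u10: MeteoState(u10=u10, T=298.15, RH=80.0, P=102500.0)


@pytest.fixture
def prokaryote():
    return PROKARYOTE


@pytest.fixture
def eukaryote():
    return EUKARYOTE


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
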