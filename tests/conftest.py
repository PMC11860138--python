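import pytest
from hypothesis import HealthCheck, settings

from alpbpk import (
    ATRACTYLODIN,
    DEFAULT_KP,
    DEFAULT_PBPK_PARAMS,
    DoseRegimen,
    build_physiology,
    simulate_pbpk,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def compound():
    return ATRACTYLODIN


@pytest.fixture(scope="session")
def physiology():
    return build_physiology(60.0, 40.0)


@pytest.fixture(scope="session")
def partition():
    return DEFAULT_KP


@pytest.fixture(scope="session")
def params():
    return DEFAULT_PBPK_PARAMS


@pytest.fixture(scope="session")
def od1000_regimen():
    return DoseRegimen(dose_mg_extract=1000.0, frequency="OD", duration_days=21)


@pytest.fixture(scope="session")
def od1000_profile(compound, physiology, partition, params, od1000_regimen):
    """Steady-state 21-day OD 1000 mg profile, shared across tests."""
    return simulate_pbpk(compound, physiology, partition, params, od1000_regimen)
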