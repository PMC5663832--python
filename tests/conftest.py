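import pytest

from iklgate import (
    RateParameters,
    SchemeVariant,
    SimulationSettings,
    build_scheme,
)


@pytest.fixture(scope="session")
def params():
    return RateParameters()


@pytest.fixture(scope="session")
def scheme(params):
    return build_scheme(params)


@pytest.fixture(scope="session")
def final_rung_scheme():
    return build_scheme(RateParameters(variant=SchemeVariant.FINAL_RUNG))


@pytest.fixture(scope="session")
def settings():
    return SimulationSettings()


@pytest.fixture(scope="session")
def family_fits(params):
    """Onset fits of the simulated activation family (shared: expensive)."""
    from iklgate.calibration import activation_family_fits

    return activation_family_fits(params)
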