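import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def boundary_model():
    """Packaged default zone boundary model (fitted once per session)."""
    from paleowear.wear_seasonality import default_boundary_model

    return default_boundary_model()


@pytest.fixture(scope="session")
def table1_rows():
    from paleowear.data_model import load_table1_assemblages

    return load_table1_assemblages()


@pytest.fixture(scope="session")
def table2_rows():
    from paleowear.data_model import load_table2_cementum

    return load_table2_cementum()


@pytest.fixture(scope="session")
def reference_populations():
    from paleowear.microwear import load_reference_populations

    return load_reference_populations()
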