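import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def spectrum():
    from augerdose.physics import default_i125_spectrum

    return default_i125_spectrum()


@pytest.fixture(scope="session")
def cell_geometry():
    from augerdose.cell_micro import CellGeometry

    return CellGeometry()


@pytest.fixture(scope="session")
def nephron_geometry():
    from augerdose.nephron_micro import NephronGeometry

    return NephronGeometry()
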