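import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mrtfrac.dose_field import IntegrationDomain, MicrobeamGeometry
from mrtfrac.lqm import CELL_LINE_PARAMS

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def geometry():
    """The study collimator: 30 µm slits, 300 µm pitch, PVDR 45.77."""
    return MicrobeamGeometry()


@pytest.fixture(scope="session")
def small_domain():
    """3 mm square patch (ten stripe periods) at the default 5 µm grid."""
    return IntegrationDomain(shape="square", extent_mm=3.0, resolution_um=5.0)


@pytest.fixture(scope="session")
def tiny_domain():
    """1.5 mm patch for fast root-finding tests."""
    return IntegrationDomain(shape="square", extent_mm=1.5, resolution_um=5.0)


@pytest.fixture(scope="session")
def a549():
    return CELL_LINE_PARAMS["A549"]


@pytest.fixture(scope="session")
def mrc5():
    return CELL_LINE_PARAMS["MRC-5"]


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)
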