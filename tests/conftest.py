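import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from deep3p.detectability import IndicatorKinetics
from deep3p.tissue_optics import TissueOpticsModel

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def uniform_tissue():
    return TissueOpticsModel.uniform(300.0)


@pytest.fixture
def gcamp8s():
    return IndicatorKinetics()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
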