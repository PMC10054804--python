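import numpy as np
import pytest

from aerodep.experiments import LPM
from aerodep.fields import AirwayDuctField
from aerodep.geometry import make_bend_geometry, make_idealized_upper_airway
from aerodep.physics import ParticleSpec


@pytest.fixture(scope="session")
def airway():
    return make_idealized_upper_airway()


@pytest.fixture(scope="session")
def bend():
    return make_bend_geometry()


@pytest.fixture(scope="session")
def airway_field_10lpm(airway):
    return AirwayDuctField(airway, 10 * LPM)


@pytest.fixture
def spec_6um():
    return ParticleSpec.from_diameter(6e-6)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
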