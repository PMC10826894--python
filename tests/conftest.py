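import numpy as np
import pytest
from hypothesis import settings

import roitsss as rt
from roitsss.sss_core import SensorArray
from roitsss.synthetic_phantom import fibonacci_sphere_array

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def helmet() -> SensorArray:
    """Default 275-channel helmet with two reference layers."""
    return rt.helmet_sensor_array()


@pytest.fixture(scope="session")
def helmet_basis(helmet):
    return rt.build_sss_basis(helmet, rt.SSSConfig())


@pytest.fixture(scope="session")
def two_shell() -> SensorArray:
    """Two dense concentric shells: a well-conditioned idealised array."""
    s1 = fibonacci_sphere_array(500, 0.08)
    s2 = fibonacci_sphere_array(500, 0.12)
    return SensorArray(
        positions=np.vstack([s1.positions, s2.positions]),
        orientations=np.vstack([s1.orientations, s2.orientations]),
    )


@pytest.fixture(scope="session")
def two_shell_basis(two_shell):
    return rt.build_sss_basis(two_shell, rt.SSSConfig())
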