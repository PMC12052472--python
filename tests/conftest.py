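import numpy as np
import pytest
import trimesh as _trimesh
from hypothesis import HealthCheck, settings

from eggscore import SynthParams, TriangleMesh, make_section, make_vgroove

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

# low-resolution sections (~5600 faces) keep mesh-heavy tests quick while
# staying above the 5000-face standard
FAST = dict(grid_resolution=6.0)


@pytest.fixture(scope="session")
def icosphere():
    """Closed unit icosphere with >= 5000 faces."""
    ico = _trimesh.creation.icosphere(subdivisions=4)
    return TriangleMesh(np.asarray(ico.vertices), np.asarray(ico.faces))


@pytest.fixture(scope="session")
def flat_section():
    """A perfectly flat disc section (all ornamentation amplitudes zero)."""
    return make_section(
        SynthParams(node_amplitude=0.0, ridge_amplitude=0.0, noise_amplitude=0.0, **FAST)
    )


@pytest.fixture(scope="session")
def vgroove_along():
    """Triangle-wave ridges running along the long axis (+Y)."""
    return make_vgroove(crest_azimuth=90.0)


@pytest.fixture(scope="session")
def vgroove_across():
    """The same ridge field rotated 90 degrees about Z."""
    return make_vgroove(crest_azimuth=0.0)


@pytest.fixture(scope="session")
def ornamented_section():
    """A generic ornamented section with nodes, ridges and noise."""
    return make_section(SynthParams(seed=3, **FAST))
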