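import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import tcdeeg
from tcdeeg.parcellation import make_toy_atlas

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def mesh():
    """Default toy cortical shell: 642-vertex icosphere at 70 mm."""
    return tcdeeg.build_toy_mesh(3, 70.0)


@pytest.fixture(scope="session")
def montage():
    return tcdeeg.place_electrodes(32, 90.0)


@pytest.fixture(scope="session")
def leadfield(mesh, montage):
    return tcdeeg.compute_lead_field(mesh, montage)


@pytest.fixture(scope="session")
def atlas(mesh):
    return make_toy_atlas(mesh, 24, seed=0)


@pytest.fixture(scope="session")
def small_setup():
    """Light 162-vertex setup for tests that rebuild many subjects."""
    mesh = tcdeeg.build_toy_mesh(2, 70.0)
    montage = tcdeeg.place_electrodes(16, 90.0)
    lf = tcdeeg.compute_lead_field(mesh, montage)
    atlas = make_toy_atlas(mesh, 8, seed=0)
    return mesh, montage, lf, atlas


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
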