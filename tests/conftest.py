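import numpy as np
import pytest

from porefield import MeshSpec, make_fixture_layout, pair_geometries

# Classic cutaneous-tumor scenario: 1300 V across a needle pair 1.6 cm
# apart (electrode radius 0.1 cm), 4 cm tissue square, 2 cm tumor circle.
CLASSIC_V = 1300.0
CLASSIC_D = 16e-3
CLASSIC_RHO0 = 1e-3


@pytest.fixture(scope="session")
def classic_layout():
    return make_fixture_layout("pair", CLASSIC_D, CLASSIC_V, electrode_radius=CLASSIC_RHO0)


@pytest.fixture(scope="session")
def classic_pair(classic_layout):
    (pair,) = pair_geometries(classic_layout)
    return pair


@pytest.fixture(scope="session")
def small_mesh(classic_layout):
    return MeshSpec(n_x=80, n_y=80, extent=classic_layout.tissue_side)


@pytest.fixture
def rng():
    return np.random.default_rng(20120102)
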