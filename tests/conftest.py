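"""Shared fixtures: montages, head models and small leadfields.

Everything is generated programmatically; session scope keeps the more
expensive objects (dense montages, leadfields) shared across tests.
"""

import numpy as np
import pytest

from neuroref.forward import HeadModel, build_leadfield, make_source_grid
from neuroref.montage import make_standard_montage


@pytest.fixture(scope="session")
def mon21():
    return make_standard_montage("ten20_21")


@pytest.fixture(scope="session")
def mon71():
    return make_standard_montage("ten10_71")


@pytest.fixture(scope="session")
def mon128():
    return make_standard_montage("dense_128")


@pytest.fixture(scope="session")
def mon256():
    return make_standard_montage("dense_256")


@pytest.fixture(scope="session")
def sphere1():
    return HeadModel.sphere1()


@pytest.fixture(scope="session")
def sphere3():
    return HeadModel.sphere3()


@pytest.fixture(scope="session")
def sphere3_equal():
    """Concentric-shell geometry with equal conductivities (reduces to sphere1)."""
    return HeadModel("sphere3", (0.87, 0.92, 1.0), (1.0, 1.0, 1.0), 92.0)


@pytest.fixture(scope="session")
def coarse_grid(sphere3):
    """Coarse source grid with 3M < 128 (full-column-rank REST regime)."""
    grid = make_source_grid(sphere3, spacing_mm=35.0)
    assert 3 * grid.n_sources < 128
    return grid


@pytest.fixture(scope="session")
def lf128_coarse(sphere3, mon128, coarse_grid):
    return build_leadfield(sphere3, mon128, coarse_grid)


@pytest.fixture(scope="session")
def lf256(sphere3, mon256):
    grid = make_source_grid(sphere3, spacing_mm=15.0)
    return build_leadfield(sphere3, mon256, grid)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
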