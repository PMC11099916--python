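import warnings

import pytest

from facetscope import SurfaceSpec, build_slab, read_cif
from facetscope.fixtures import FIXTURE_KINDS, make_fixture
from facetscope.topology import classify_surface_atoms, compute_topology


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """All synthetic crystal fixtures, generated once per session."""
    d = tmp_path_factory.mktemp("fixtures")
    for kind in FIXTURE_KINDS:
        make_fixture(kind, seed=0, out_dir=d)
    return d


def _read(d, kind):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return read_cif(d / f"{kind}.cif")


@pytest.fixture(scope="session")
def ar_crystal(fixture_dir):
    return _read(fixture_dir, "noble_cubic")


@pytest.fixture(scope="session")
def toyacid_crystal(fixture_dir):
    return _read(fixture_dir, "toyacid")


@pytest.fixture(scope="session")
def catemer_crystal(fixture_dir):
    return _read(fixture_dir, "catemer")


@pytest.fixture(scope="session")
def flatring_crystal(fixture_dir):
    return _read(fixture_dir, "flatring")


@pytest.fixture(scope="session")
def layered_crystal(fixture_dir):
    return _read(fixture_dir, "layered_polar")


@pytest.fixture(scope="session")
def toyacid_slab(toyacid_crystal):
    return build_slab(toyacid_crystal, SurfaceSpec((0, 0, 1), 0.0))


@pytest.fixture(scope="session")
def toyacid_mesh(toyacid_slab):
    return compute_topology(toyacid_slab)


@pytest.fixture(scope="session")
def toyacid_surface(toyacid_slab, toyacid_mesh):
    return classify_surface_atoms(toyacid_slab, toyacid_mesh)
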