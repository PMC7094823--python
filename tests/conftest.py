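import numpy as np
import pytest

from splicesim.geometry import (
    GeometryConfig,
    LatticeSpec,
    SiteLattice,
    SiteType,
    build_cell,
)


@pytest.fixture(scope="session")
def small_cell_config():
    """A miniature but complete cell: every organelle present, fast to build."""
    return GeometryConfig(
        edge_length=6.4,
        spacing=0.1,
        cell_radius=3.0,
        nuclear_radius=1.6,
        membrane_thickness=0.2,
        npc_density=7.0,
        n_speckles=4,
        speckle_radius=0.18,
        n_cajal=1,
        cajal_radius=0.25,
        n_mitochondria=25,
        mito_length=0.5,
        mito_diameter=0.3,
        er_fraction=0.03,
        golgi_sheets=2,
        n_genes=6,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cell(small_cell_config):
    return build_cell(small_cell_config)


def make_uniform_box(edge=1.92, spacing=0.064, site_type=SiteType.NUCLEOPLASM):
    lat = SiteLattice.empty(LatticeSpec(edge, spacing))
    lat.sites[:] = int(site_type)
    return lat


@pytest.fixture()
def uniform_box():
    return make_uniform_box()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
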