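import numpy as np
import pytest

import scomber as sc
from scomber.population import SuperIndividual, Stage, make_si_rng, structural_mass
from scomber.seascape import Seascape
from scomber.synthetic_fixtures import FixtureSpec, make_world_small


@pytest.fixture(scope="session")
def params():
    return sc.load_parameters(None)


@pytest.fixture(scope="session")
def small_config():
    """The standard reduced test world: 40x40 grid, 105 SIs, 5 years."""
    return make_world_small(FixtureSpec(spinup_years=2, run_years=3))


@pytest.fixture(scope="session")
def small_run(small_config):
    """One completed 5-year reference run, shared across tests."""
    return sc.run(small_config, seed=7)


@pytest.fixture
def open_sea(params):
    """A 20x20 all-ocean seascape with uniform benign conditions."""
    ny = nx = 20
    sea = Seascape(
        depth=np.full((ny, nx), -2000.0),
        lat=np.full((ny, nx), 55.0),
        lon=np.zeros((ny, nx)),
    )
    sea.X = np.full((ny, nx), 2.0)
    sea.SST = np.full((ny, nx), params.T_ref - 273.15)
    sea.p_photo = np.full((ny, nx), 0.8)
    return sea


def make_adult(params, L=30.0, x=5.0, y=5.0, sid=0, seed=0, abundance=1e6):
    si = SuperIndividual(
        id=sid,
        abundance=abundance,
        age_days=6 * 365.0,
        gender="f",
        stage=Stage.ADULT,
        L=L,
        M_struct=structural_mass(L, params),
        energy_reserve=0.5 * params.E_max * structural_mass(L, params) * params.E_lipid,
        x=x,
        y=y,
        rng=make_si_rng(seed, sid),
    )
    si.fed_once = True
    return si
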