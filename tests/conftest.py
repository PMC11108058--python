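import numpy as np
import pytest

import csfdrift as cd


@pytest.fixture(scope="session")
def coarse_grid():
    return cd.Grid3D(Nx=61, Neta=17, Ns=24)


@pytest.fixture(scope="session")
def const_ecc(coarse_grid):
    return cd.make_constant_eccentricity(coarse_grid)


@pytest.fixture(scope="session")
def var_ecc(coarse_grid):
    return cd.make_variable_eccentricity(coarse_grid)


@pytest.fixture(scope="session")
def osc_const(const_ecc, coarse_grid):
    """Oscillatory solution on the constant-eccentricity canal, alpha=3, k=0.5."""
    return cd.assemble_solution(const_ecc, 3.0, 0.5, coarse_grid)


@pytest.fixture(scope="session")
def osc_var(var_ecc, coarse_grid):
    return cd.assemble_solution(var_ecc, 3.0, 0.5, coarse_grid)


@pytest.fixture(scope="session")
def mean_const(osc_const):
    return cd.lagrangian_mean_flow(osc_const)


@pytest.fixture(scope="session")
def mean_var(osc_var):
    return cd.lagrangian_mean_flow(osc_var)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240417)
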