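import numpy as np
import pytest

from carbonbook import (
    GridSpec, TimeConstantTable, TransitionForcing, initialize_equilibrium,
)
from carbonbook.core import J_V, J_S, J_C, J_P, N_COVER, N_PFT


@pytest.fixture
def small_grid():
    return GridSpec.regular(3, 4, lat_min=48.0, lat_max=51.0,
                            lon_min=8.0, lon_max=12.0)


@pytest.fixture
def tau_default():
    return TimeConstantTable.default()


def make_state(grid, rho_v=100.0, rho_s=80.0, frac=None, pft=None, year=1999):
    """Equilibrium world: uniform primary/secondary densities, no excess."""
    n = grid.n_cell
    if frac is None:
        frac = np.zeros((n, N_COVER))
        frac[:, J_V], frac[:, J_S], frac[:, J_C], frac[:, J_P] = .4, .3, .2, .1
    if pft is None:
        pft = np.full((n, N_PFT), 1.0 / N_PFT)
    area = grid.cell_area
    stocks = np.zeros((n, N_COVER, N_PFT))
    stocks[:, J_V, :] = rho_v * area[:, None] * frac[:, [J_V]] * pft
    stocks[:, J_S, :] = rho_s * area[:, None] * frac[:, [J_S]] * pft
    return initialize_equilibrium(stocks, grid, frac, pft, year=year)


@pytest.fixture
def small_state(small_grid):
    return make_state(small_grid)


def zero_forcing(years, n_cell):
    return TransitionForcing.zeros(years, n_cell)
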