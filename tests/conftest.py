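"""Shared fixtures: small grids and a converged Born reference solve.

Expensive SCRF solves are session-scoped so several tests can interrogate
one converged solution.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from gpesolv.dielectric import DielectricModel
from gpesolv.grid import ScalarField, UniformGrid
from gpesolv.scrf import SCRFConfig, solve_reaction_potential
from gpesolv.solvation import born_system, build_grid, gaussian_density


@pytest.fixture(autouse=True)
def _quiet_face_decay():
    # deliberately small test boxes trip the padding advisory; keep the
    # test output readable
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="density is not negligible")
        yield


@pytest.fixture
def small_grid() -> UniformGrid:
    """16^3 grid, spacing 0.5 bohr, centered on the origin."""
    n, h = 16, 0.5
    return UniformGrid((-0.5 * h * (n - 1),) * 3, h, (n,) * 3)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230318)


def _centered_grid(n: int, h: float) -> UniformGrid:
    return UniformGrid((-0.5 * h * (n - 1),) * 3, h, (n,) * 3)


@pytest.fixture(scope="session")
def born_setup():
    """Well-resolved small Born system: q=1 in an R=2 sphere, sigma=0.4,
    eps_out=80, on a 0.25-bohr grid with 6 bohr padding."""
    mol, cav = born_system(q=1.0, radius=2.0, sigma=0.4, width=0.5)
    grid = build_grid(cav, 0.25, 6.0)
    rho = gaussian_density(mol, grid)
    model = DielectricModel(cav, eps_out=80.0)
    return mol, cav, grid, rho, model


@pytest.fixture(scope="session")
def born_solution(born_setup):
    """Converged reaction potential for the shared Born system."""
    mol, cav, grid, rho, model = born_setup
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        V_R, state = solve_reaction_potential(
            rho, model, SCRFConfig(delta=1e-6, max_microiter=100)
        )
    return V_R, state


def gaussian_field(grid: UniformGrid, center, width: float, amplitude: float = 1.0) -> ScalarField:
    """Normalized-amplitude Gaussian bump helper used across test modules."""
    X, Y, Z = grid.meshgrid()
    r2 = (X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2
    return ScalarField(grid, amplitude * np.exp(-r2 / (width * width)))
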