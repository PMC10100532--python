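"""Interlocking-spheres molecular cavity with a diffuse boundary.

The cavity function C(r) is a smooth indicator of the solute region:
1 deep inside the union of atom-centered spheres, 0 far outside, with a
boundary layer of width sigma.  Each sphere's effective radius is

    R_i = alpha * R_i^vdW + beta * sigma

so that alpha scales the van der Waals radius and beta pushes the
boundary midpoint outward by a fraction of its own width.  A single
sphere's profile is the complementary-error-function sigmoid of the
signed distance s = |r - c| - R,

    C_i(r) = 1/2 * erfc(s_i(r) / sigma),

which tends to the Heaviside step as sigma -> 0.  Spheres combine by the
complement product

    C(r) = 1 - prod_i (1 - C_i(r)),

which reduces to C_i for one sphere and stays 1 anywhere deep inside
*any* sphere.  The gradient of C is available in closed form (product
rule over the complement product), avoiding finite-difference noise in
the dielectric boundary where it matters most.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import erfc

from .grid import ScalarField, UniformGrid, VectorField
from .molecule import Molecule, bondi_radius

__all__ = [
    "CavityParams",
    "CavitySphere",
    "Cavity",
    "effective_radius",
    "signed_distance",
    "sphere_boundary",
    "sphere_boundary_derivative",
    "cavity_function",
    "cavity_gradient",
    "cavity_from_molecule",
]

_SQRT_PI = float(np.sqrt(np.pi))


@dataclass(frozen=True)
class CavityParams:
    """Cavity shape parameters: radius scale alpha, offset multiplier beta,
    boundary width sigma (bohr).  Defaults are the production defaults
    alpha=1.1, beta=0.5, sigma=0.2 au."""

    alpha: float = 1.1
    beta: float = 0.5
    sigma: float = 0.2

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if self.alpha <= 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")


def effective_radius(vdw_radius: float, params: CavityParams) -> float:
    """Effective sphere radius alpha*R_vdw + beta*sigma (bohr)."""
    if vdw_radius <= 0:
        raise ValueError(f"vdw_radius must be > 0, got {vdw_radius}")
    r = params.alpha * vdw_radius + params.beta * params.sigma
    if r <= 0:
        raise ValueError("effective radius came out non-positive; check alpha/beta/sigma")
    return float(r)


@dataclass(frozen=True)
class CavitySphere:
    """One smoothed sphere: center (bohr), vdW radius and the effective
    radius derived from the cavity parameters."""

    center: tuple[float, float, float]
    vdw_radius: float
    effective_radius: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))
        if self.effective_radius <= 0:
            raise ValueError("effective_radius must be positive")

    @classmethod
    def from_vdw(cls, center, vdw_radius: float, params: CavityParams) -> "CavitySphere":
        return cls(tuple(center), float(vdw_radius), effective_radius(vdw_radius, params))


@dataclass(frozen=True)
class Cavity:
    """An ordered collection of smoothed spheres plus global parameters.

    One (alpha, beta, sigma) triple applies to all spheres by default;
    per-sphere radii are already baked into each CavitySphere, so a
    caller needing per-sphere overrides constructs the spheres directly.
    """

    spheres: tuple[CavitySphere, ...]
    params: CavityParams

    def __post_init__(self) -> None:
        object.__setattr__(self, "spheres", tuple(self.spheres))
        if not self.spheres:
            raise ValueError("a cavity needs at least one sphere")

    @property
    def sigma(self) -> float:
        return self.params.sigma

    def with_sigma(self, sigma: float) -> "Cavity":
        """Same sphere geometry re-derived with a different boundary width."""
        params = replace(self.params, sigma=sigma)
        spheres = tuple(
            CavitySphere.from_vdw(s.center, s.vdw_radius, params) for s in self.spheres
        )
        return Cavity(spheres, params)


def cavity_from_molecule(
    mol: Molecule,
    params: CavityParams | None = None,
    radius_overrides: dict[str, float] | None = None,
    atom_radii: dict[int, float] | None = None,
) -> Cavity:
    """Atom-centered cavity from Bondi radii (bohr), with optional
    per-element (``radius_overrides``) and per-atom (``atom_radii``,
    keyed by atom index) radius overrides in bohr."""
    params = params or CavityParams()
    spheres = []
    for i, (sym, pos) in enumerate(zip(mol.symbols, mol.positions)):
        if atom_radii and i in atom_radii:
            rvdw = float(atom_radii[i])
        else:
            rvdw = bondi_radius(sym, radius_overrides)
        spheres.append(CavitySphere.from_vdw(pos, rvdw, params))
    return Cavity(tuple(spheres), params)


def signed_distance(points: np.ndarray, sphere: CavitySphere) -> np.ndarray:
    """Signed normal distance |r - c| - R: negative inside, positive outside.

    ``points`` is (..., 3); broadcast over leading axes.
    """
    d = np.linalg.norm(np.asarray(points, dtype=float) - np.asarray(sphere.center), axis=-1)
    return d - sphere.effective_radius


def sphere_boundary(s, sigma: float):
    """Smoothed boundary profile C_a(s) = 1/2 erfc(s/sigma) in [0, 1]."""
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    return 0.5 * erfc(np.asarray(s, dtype=float) / sigma)


def sphere_boundary_derivative(s, sigma: float):
    """dC_a/ds = -exp(-(s/sigma)^2) / (sigma sqrt(pi))."""
    s = np.asarray(s, dtype=float)
    return -np.exp(-((s / sigma) ** 2)) / (sigma * _SQRT_PI)


def _sphere_fields(grid: UniformGrid, cavity: Cavity):
    """Per-sphere signed distance s_i and radial distance d_i on the grid."""
    X, Y, Z = grid.meshgrid(sparse=True)
    for sph in cavity.spheres:
        cx, cy, cz = sph.center
        d = np.sqrt((X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2)
        yield sph, d, d - sph.effective_radius


def cavity_function(grid: UniformGrid, cavity: Cavity) -> ScalarField:
    """Molecular cavity function C = 1 - prod_i (1 - C_i) on the grid."""
    hole = np.ones(grid.shape)  # running product of (1 - C_i)
    for sph, _d, s in _sphere_fields(grid, cavity):
        hole *= 1.0 - sphere_boundary(s, cavity.sigma)
    return ScalarField(grid, 1.0 - hole)


def cavity_gradient(grid: UniformGrid, cavity: Cavity) -> VectorField:
    """Closed-form gradient of the cavity function.

    Product rule over the complement product:

        grad C = sum_i (dC_i/ds) u_i * prod_{j != i} (1 - C_j)

    with u_i the unit radial vector from sphere i's center.  The partial
    products are accumulated as prefix/suffix products so no division by
    a vanishing (1 - C_i) occurs deep inside a sphere.  At an exact
    sphere center the radial direction is undefined; the contribution is
    set to zero there (the profile derivative already vanishes to
    machine precision for R >> sigma).
    """
    n = len(cavity.spheres)
    per_sphere = list(_sphere_fields(grid, cavity))
    one_minus = [1.0 - sphere_boundary(s, cavity.sigma) for _, _, s in per_sphere]

    # prefix[i] = prod_{j<i}(1-C_j); suffix accumulated in the second pass
    prefix = np.ones(grid.shape)
    prefixes = []
    for i in range(n):
        prefixes.append(prefix.copy())
        prefix *= one_minus[i]

    X, Y, Z = grid.meshgrid(sparse=True)
    out = np.zeros((*grid.shape, 3))
    suffix = np.ones(grid.shape)
    for i in range(n - 1, -1, -1):
        sph, d, s = per_sphere[i]
        weight = prefixes[i] * suffix
        dcds = sphere_boundary_derivative(s, cavity.sigma)
        # grad C_i = (dC_i/ds) * u_i ; u undefined at d = 0 -> zero contribution
        inv_d = np.where(d > 1e-12, 1.0 / np.maximum(d, 1e-300), 0.0)
        coeff = dcds * weight * inv_d
        cx, cy, cz = sph.center
        out[..., 0] += coeff * (X - cx)
        out[..., 1] += coeff * (Y - cy)
        out[..., 2] += coeff * (Z - cz)
        suffix *= one_minus[i]
    return VectorField(grid, out)
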