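"""Uniform Cartesian grids and scalar/vector fields in atomic units.

Everything downstream (cavity functions, permittivities, densities,
potentials) lives on a :class:`UniformGrid`: an axis-aligned box with
isotropic spacing, all lengths in bohr.  The grid replaces an adaptive
multiresolution basis with a fixed discretization whose accuracy is
controlled explicitly by the spacing and the box padding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "UniformGrid",
    "ScalarField",
    "VectorField",
    "GridMismatchError",
    "integrate",
    "inner_product",
    "gradient",
    "divergence",
]


class GridMismatchError(ValueError):
    """Two fields that must share a grid do not."""


@dataclass(frozen=True)
class UniformGrid:
    """Axis-aligned uniform grid: ``origin + spacing * (i, j, k)``.

    Parameters
    ----------
    origin:
        Position of node ``(0, 0, 0)`` in bohr.
    spacing:
        Isotropic node spacing in bohr, ``> 0``.
    shape:
        Number of nodes along each axis; each component must be >= 8 so
        that central differences have a meaningful interior.
    """

    origin: tuple[float, float, float]
    spacing: float
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", tuple(float(x) for x in self.origin))
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        if len(self.origin) != 3 or len(self.shape) != 3:
            raise ValueError("origin and shape must have 3 components")
        if not np.isfinite(self.origin).all():
            raise ValueError("grid origin must be finite")
        if self.spacing <= 0:
            raise ValueError(f"grid spacing must be positive, got {self.spacing}")
        if any(n < 8 for n in self.shape):
            raise ValueError(f"every grid dimension must be >= 8, got {self.shape}")

    @property
    def cell_volume(self) -> float:
        return self.spacing**3

    @property
    def n_nodes(self) -> int:
        return int(np.prod(self.shape))

    @property
    def extent(self) -> np.ndarray:
        """Box edge lengths (node span) in bohr, shape (3,)."""
        return self.spacing * (np.asarray(self.shape) - 1)

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """1-D node coordinate arrays along x, y, z."""
        return tuple(
            self.origin[d] + self.spacing * np.arange(self.shape[d]) for d in range(3)
        )

    def meshgrid(self, sparse: bool = True):
        """Node coordinates as (sparse by default) broadcastable arrays."""
        return np.meshgrid(*self.axes(), indexing="ij", sparse=sparse)

    def points(self) -> np.ndarray:
        """All node coordinates as an ``(n_nodes, 3)`` array (C order)."""
        X, Y, Z = self.meshgrid(sparse=False)
        return np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    def zeros(self) -> "ScalarField":
        return ScalarField(self, np.zeros(self.shape))


def _require_same_grid(a, b) -> None:
    if a.grid != b.grid:
        raise GridMismatchError(
            f"fields live on different grids: {a.grid} vs {b.grid}"
        )


@dataclass
class ScalarField:
    """Real scalar field sampled on the nodes of a :class:`UniformGrid`."""

    grid: UniformGrid
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise GridMismatchError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if not np.isfinite(self.values).all():
            raise ValueError("scalar field contains non-finite values")

    # -- arithmetic (grid-checked, returns new fields) -------------------
    def __add__(self, other: "ScalarField") -> "ScalarField":
        _require_same_grid(self, other)
        return ScalarField(self.grid, self.values + other.values)

    def __sub__(self, other: "ScalarField") -> "ScalarField":
        _require_same_grid(self, other)
        return ScalarField(self.grid, self.values - other.values)

    def __mul__(self, scalar: float) -> "ScalarField":
        return ScalarField(self.grid, self.values * float(scalar))

    __rmul__ = __mul__

    def __neg__(self) -> "ScalarField":
        return ScalarField(self.grid, -self.values)

    def norm(self) -> float:
        """L2 field norm sqrt(integral of f**2)."""
        return float(np.sqrt(np.sum(self.values**2) * self.grid.cell_volume))

    def max_abs(self) -> float:
        return float(np.abs(self.values).max())


@dataclass
class VectorField:
    """3-component vector field on a uniform grid; components stacked last."""

    grid: UniformGrid
    values: np.ndarray = field(repr=False)  # shape (*grid.shape, 3)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (*self.grid.shape, 3):
            raise GridMismatchError(
                f"vector values shape {self.values.shape} != {(*self.grid.shape, 3)}"
            )
        if not np.isfinite(self.values).all():
            raise ValueError("vector field contains non-finite values")

    def dot(self, other: "VectorField") -> ScalarField:
        """Pointwise scalar product of two vector fields."""
        _require_same_grid(self, other)
        return ScalarField(self.grid, np.einsum("...i,...i->...", self.values, other.values))

    def magnitude(self) -> ScalarField:
        return ScalarField(self.grid, np.linalg.norm(self.values, axis=-1))

    def __add__(self, other: "VectorField") -> "VectorField":
        _require_same_grid(self, other)
        return VectorField(self.grid, self.values + other.values)

    def __sub__(self, other: "VectorField") -> "VectorField":
        _require_same_grid(self, other)
        return VectorField(self.grid, self.values - other.values)

    def __mul__(self, scalar: float) -> "VectorField":
        return VectorField(self.grid, self.values * float(scalar))

    __rmul__ = __mul__


def integrate(f: ScalarField) -> float:
    """Riemann-sum integral of ``f`` over the box: sum(values) * h^3."""
    return float(np.sum(f.values) * f.grid.cell_volume)


def inner_product(f: ScalarField, g: ScalarField) -> float:
    """L2 inner product <f, g> = integral of f*g (Riemann sum)."""
    _require_same_grid(f, g)
    return float(np.sum(f.values * g.values) * f.grid.cell_volume)


def gradient(f: ScalarField) -> VectorField:
    """Finite-difference gradient: second-order central differences in the
    interior, one-sided at the box faces (``numpy.gradient`` convention)."""
    g = np.gradient(f.values, f.grid.spacing, edge_order=1)
    return VectorField(f.grid, np.stack(g, axis=-1))


def divergence(v: VectorField) -> ScalarField:
    """Finite-difference divergence, same stencils as :func:`gradient`."""
    h = v.grid.spacing
    out = np.zeros(v.grid.shape)
    for d in range(3):
        out += np.gradient(v.values[..., d], h, axis=d, edge_order=1)
    return ScalarField(v.grid, out)
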