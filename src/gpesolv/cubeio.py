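"""Gaussian cube file output/input for grid scalar fields.

The de-facto standard cube layout is used: all quantities in atomic
units, orthogonal voxel axes, values in z-fastest order, six per line.
Orbital cubes (negative atom count in the header) are a different
dialect and are rejected explicitly on read.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .grid import ScalarField, UniformGrid
from .molecule import ATOMIC_NUMBERS, Molecule

__all__ = ["write_cube", "read_cube", "CubeParseError"]


class CubeParseError(ValueError):
    pass


def write_cube(f: ScalarField, mol: Molecule, path, comment: str = "gpesolv scalar field") -> None:
    """Write ``f`` (and atom records from ``mol``) as a Gaussian cube file."""
    g = f.grid
    lines = [comment, "grid scalar field in atomic units (z-fastest)"]
    lines.append(_rec(mol.n_atoms, *g.origin))
    for d in range(3):
        axis = [0.0, 0.0, 0.0]
        axis[d] = g.spacing
        lines.append(_rec(g.shape[d], *axis))
    for sym, q, pos in zip(mol.symbols, mol.charges, mol.positions):
        z = ATOMIC_NUMBERS.get(sym, 0)
        lines.append(f"{z:5d}{q:12.6f}{pos[0]:12.6f}{pos[1]:12.6f}{pos[2]:12.6f}")
    flat = f.values.ravel(order="C")  # C order == z fastest for (nx, ny, nz)
    for start in range(0, flat.size, 6):
        chunk = flat[start : start + 6]
        lines.append("".join(f"{v:13.5E}" for v in chunk))
    Path(path).write_text("\n".join(lines) + "\n")


def _rec(n: int, x: float, y: float, z: float) -> str:
    return f"{n:5d}{x:12.6f}{y:12.6f}{z:12.6f}"


def read_cube(path) -> tuple[ScalarField, Molecule]:
    """Read a standard cube file back into (field, molecule).

    Only the orthogonal, isotropic, positive-atom-count dialect written
    by :func:`write_cube` (and most visualizers) is accepted.
    """
    lines = Path(path).read_text().splitlines()
    if len(lines) < 6:
        raise CubeParseError(f"{path}: truncated cube header")
    try:
        parts = lines[2].split()
        natoms = int(parts[0])
        origin = tuple(float(p) for p in parts[1:4])
        shape = []
        spacing = None
        for d in range(3):
            p = lines[3 + d].split()
            n = int(p[0])
            if n <= 0:
                raise CubeParseError(
                    f"{path}: non-positive axis count {n}; MO/negative-natoms "
                    "cube dialects are not supported"
                )
            axis = np.array([float(x) for x in p[1:4]])
            h = axis[d]
            if spacing is None:
                spacing = h
            off_diag = np.delete(axis, d)
            if abs(h - spacing) > 1e-9 * max(abs(h), 1.0) or np.any(np.abs(off_diag) > 1e-12):
                raise CubeParseError(f"{path}: only isotropic orthogonal cube axes are supported")
            shape.append(n)
    except (ValueError, IndexError) as exc:
        raise CubeParseError(f"{path}: malformed cube header: {exc}") from None
    if natoms < 0:
        raise CubeParseError(
            f"{path}: negative atom count (orbital-cube dialect) is not supported"
        )

    symbols, charges, positions = [], [], []
    z_to_sym = {z: s for s, z in ATOMIC_NUMBERS.items()}
    for i in range(natoms):
        p = lines[6 + i].split()
        z = int(p[0])
        symbols.append(z_to_sym.get(z, "X"))
        charges.append(float(p[1]))
        positions.append([float(x) for x in p[2:5]])

    data = np.array(" ".join(lines[6 + natoms :]).split(), dtype=float)
    nvals = int(np.prod(shape))
    if data.size != nvals:
        raise CubeParseError(f"{path}: expected {nvals} values, found {data.size}")
    grid = UniformGrid(origin, float(spacing), tuple(shape))
    fld = ScalarField(grid, data.reshape(shape))
    if natoms == 0:
        mol = Molecule([], np.empty((0, 3)), np.empty(0), np.empty(0))
    else:
        mol = Molecule(symbols, np.array(positions), np.array(charges))
    return fld, mol
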