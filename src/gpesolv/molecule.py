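"""Molecular geometries: XYZ input and element data (charges, Bondi radii).

A :class:`Molecule` is the classical stand-in for a quantum solute: each
atom carries a point charge that is later smeared into a normalized
Gaussian to build a smooth density on the grid.  Positions are stored in
bohr; XYZ files are read in angstrom by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ANGSTROM_TO_BOHR",
    "BONDI_RADII_ANGSTROM",
    "ATOMIC_NUMBERS",
    "Molecule",
    "XYZParseError",
    "UnknownElementError",
    "read_xyz",
    "bondi_radius",
]

ANGSTROM_TO_BOHR = 1.8897261246

# Bondi van der Waals radii in angstrom (Bondi 1964 set, with the common
# later additions for H-group and heavier halogens).  Converted to bohr at
# the point of use; cavity spheres default to these.
BONDI_RADII_ANGSTROM: dict[str, float] = {
    "H": 1.20, "He": 1.40,
    "Li": 1.82, "Be": 1.53, "B": 1.92, "C": 1.70, "N": 1.55, "O": 1.52,
    "F": 1.47, "Ne": 1.54,
    "Na": 2.27, "Mg": 1.73, "Al": 1.84, "Si": 2.10, "P": 1.80, "S": 1.80,
    "Cl": 1.75, "Ar": 1.88,
    "K": 2.75, "Ca": 2.31, "Ga": 1.87, "Ge": 2.11, "As": 1.85, "Se": 1.90,
    "Br": 1.85, "Kr": 2.02,
    "Rb": 3.03, "Sr": 2.49, "In": 1.93, "Sn": 2.17, "Sb": 2.06, "Te": 2.06,
    "I": 1.98, "Xe": 2.16,
}

ATOMIC_NUMBERS: dict[str, int] = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18, "K": 19, "Ca": 20, "Ga": 31, "Ge": 32,
    "As": 33, "Se": 34, "Br": 35, "Kr": 36, "Rb": 37, "Sr": 38, "In": 49,
    "Sn": 50, "Sb": 51, "Te": 52, "I": 53, "Xe": 54,
}

#: Default Gaussian smearing width for classical point charges, bohr.
#: Resolvable at the default 0.2 bohr grid spacing while keeping
#: essentially all of the charge well inside a scaled Bondi sphere.
DEFAULT_SMEARING_WIDTH = 0.4


class XYZParseError(ValueError):
    """Malformed XYZ file; the message names the offending line."""


class UnknownElementError(KeyError):
    """Element symbol with no tabulated radius and no user override."""


@dataclass
class Molecule:
    """Atoms with positions (bohr), charges (e) and smearing widths (bohr)."""

    symbols: list[str]
    positions: np.ndarray  # (n, 3) bohr
    charges: np.ndarray  # (n,) e
    widths: np.ndarray = field(default=None)  # (n,) bohr

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.charges = np.atleast_1d(np.asarray(self.charges, dtype=float))
        if self.widths is None:
            self.widths = np.full(len(self.symbols), DEFAULT_SMEARING_WIDTH)
        self.widths = np.atleast_1d(np.asarray(self.widths, dtype=float))
        n = len(self.symbols)
        if self.positions.shape != (n, 3):
            raise ValueError(f"positions shape {self.positions.shape} != ({n}, 3)")
        if self.charges.shape != (n,) or self.widths.shape != (n,):
            raise ValueError("charges/widths length must match number of atoms")
        if not np.isfinite(self.positions).all():
            raise ValueError("atom positions must be finite")
        if (self.widths <= 0).any():
            raise ValueError("Gaussian smearing widths must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum())

    def translated(self, shift) -> "Molecule":
        """Rigidly shifted copy (shift in bohr)."""
        return Molecule(
            list(self.symbols),
            self.positions + np.asarray(shift, dtype=float),
            self.charges.copy(),
            self.widths.copy(),
        )


def bondi_radius(symbol: str, overrides: dict[str, float] | None = None) -> float:
    """Van der Waals radius in bohr for an element symbol.

    ``overrides`` maps element symbols to radii in bohr and takes
    precedence over the built-in Bondi table.
    """
    if overrides and symbol in overrides:
        return float(overrides[symbol])
    try:
        return BONDI_RADII_ANGSTROM[symbol] * ANGSTROM_TO_BOHR
    except KeyError:
        raise UnknownElementError(
            f"no van der Waals radius tabulated for element {symbol!r}; "
            "supply a per-element radius override"
        ) from None


def read_xyz(path, units: str = "angstrom") -> Molecule:
    """Read a standard XYZ file into a :class:`Molecule`.

    Layout: atom-count line, comment line, then one ``El x y z`` line per
    atom.  An optional 5th column supplies the per-atom charge; otherwise
    charges default to the element's nuclear charge.  ``units`` selects
    the coordinate unit of the file (``"angstrom"`` default, ``"bohr"``);
    positions are always stored in bohr.
    """
    if units not in ("angstrom", "bohr"):
        raise ValueError(f"units must be 'angstrom' or 'bohr', got {units!r}")
    scale = ANGSTROM_TO_BOHR if units == "angstrom" else 1.0

    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].strip():
        raise XYZParseError(f"{path}: empty file, expected an atom count on line 1")
    try:
        natoms = int(lines[0].split()[0])
    except ValueError:
        raise XYZParseError(
            f"{path}: line 1 must start with the atom count, got {lines[0]!r}"
        ) from None
    if len(lines) < natoms + 2:
        raise XYZParseError(
            f"{path}: header promises {natoms} atoms but only "
            f"{max(len(lines) - 2, 0)} atom lines are present"
        )

    symbols: list[str] = []
    positions = np.empty((natoms, 3))
    charges = np.empty(natoms)
    for i in range(natoms):
        lineno = i + 3
        parts = lines[i + 2].split()
        if len(parts) < 4:
            raise XYZParseError(
                f"{path}: line {lineno}: expected 'El x y z [charge]', got "
                f"{lines[i + 2]!r}"
            )
        sym = parts[0].capitalize()
        try:
            positions[i] = [float(p) for p in parts[1:4]]
        except ValueError:
            raise XYZParseError(
                f"{path}: line {lineno}: non-numeric coordinate in {lines[i + 2]!r}"
            ) from None
        if len(parts) >= 5:
            try:
                charges[i] = float(parts[4])
            except ValueError:
                raise XYZParseError(
                    f"{path}: line {lineno}: non-numeric charge column "
                    f"{parts[4]!r}"
                ) from None
        else:
            if sym not in ATOMIC_NUMBERS:
                raise UnknownElementError(
                    f"{path}: line {lineno}: unknown element {sym!r} and no "
                    "explicit charge column"
                )
            charges[i] = ATOMIC_NUMBERS[sym]
        symbols.append(sym)

    return Molecule(symbols, positions * scale, charges)
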