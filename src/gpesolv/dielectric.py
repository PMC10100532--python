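"""Position-dependent permittivity built on the cavity function.

The permittivity interpolates exponentially between the interior value
eps_in (where C = 1) and the bulk solvent value eps_out (where C = 0):

    eps(r) = eps_in * exp[(1 - C(r)) * ln(eps_out / eps_in)]

The exponential form makes the log-derivative — the only way the
permittivity enters the iterative solver — a simple multiple of the
cavity gradient:

    grad log eps = -ln(eps_out / eps_in) * grad C
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log

import numpy as np

from .cavity import Cavity, cavity_function, cavity_gradient
from .grid import ScalarField, UniformGrid, VectorField, gradient

__all__ = ["DielectricModel", "permittivity_field", "log_derivative_field"]

_C_TOL = 1e-8


@dataclass(frozen=True)
class DielectricModel:
    """Inside/outside permittivities plus the cavity that interpolates them.

    eps_in defaults to 1 (vacuum inside the cavity); eps_out = eps_in is
    the homogeneous limit in which no reaction field arises.
    """

    cavity: Cavity
    eps_out: float
    eps_in: float = 1.0

    def __post_init__(self) -> None:
        if self.eps_in <= 0 or self.eps_out <= 0:
            raise ValueError("permittivities must be positive")

    @property
    def log_ratio(self) -> float:
        return log(self.eps_out / self.eps_in)

    @property
    def is_homogeneous(self) -> bool:
        return self.eps_out == self.eps_in

    # convenience: evaluate everything a solver needs on one grid
    def fields(self, grid: UniformGrid) -> tuple[ScalarField, ScalarField, VectorField]:
        """(C, eps, grad log eps) evaluated on ``grid``; the log-derivative
        uses the closed-form cavity gradient."""
        C = cavity_function(grid, self.cavity)
        eps = permittivity_field(C, self)
        grad_log_eps = log_derivative_field(C, cavity_gradient(grid, self.cavity), self)
        return C, eps, grad_log_eps


def permittivity_field(C: ScalarField, model: DielectricModel) -> ScalarField:
    """Exponential permittivity eps(r) from the cavity function C."""
    c = C.values
    if c.min() < -_C_TOL or c.max() > 1.0 + _C_TOL:
        raise ValueError(
            f"cavity function out of [0, 1]: min {c.min():.3e}, max {c.max():.3e}"
        )
    c = np.clip(c, 0.0, 1.0)
    return ScalarField(C.grid, model.eps_in * np.exp((1.0 - c) * model.log_ratio))


def log_derivative_field(
    C: ScalarField, gradC: VectorField, model: DielectricModel | None = None, *, numerical: bool = False
) -> VectorField:
    """grad log eps = -ln(eps_out/eps_in) * grad C.

    With ``numerical=True`` the analytic relation is ignored and the
    log-derivative is taken by finite differences of log eps(C) — the
    fallback for user-supplied cavity fields with no closed-form gradient.
    """
    if numerical:
        log_eps = ScalarField(C.grid, np.log(permittivity_field(C, model).values))
        return gradient(log_eps)
    return (-model.log_ratio) * gradC
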