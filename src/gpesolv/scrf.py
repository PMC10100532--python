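"""Self-consistent reaction field: iterative solution of the generalized
Poisson equation (GPE) with a position-dependent permittivity.

The GPE  div(eps grad V) = -4 pi rho  is rewritten as an ordinary
Poisson problem with two extra source terms: the *effective charge*
rho_eff = rho / eps and the *polarization function*

    gamma = (1/4 pi) grad(log eps) . grad V .

Splitting V = V_rho + V_R (vacuum potential + reaction potential) and
inverting the Laplacian with the free-space Coulomb kernel G gives the
fixed-point equation solved here by microiterations:

    V_R = G[ (rho_eff - rho) + gamma(V_rho + V_R) ] .

Each microiteration evaluates the total potential, gamma, one kernel
application, and a KAIN-accelerated update; convergence is checked on
the L2 field norm of the reaction-potential update against a threshold
delta.  ``macro_driver`` emulates the outer self-consistent-field loop
this solver is normally nested in: a sequence of densities with
shrinking update norms, with the four guess/threshold regimes

    A: zero guess each macroiteration   C: fixed threshold delta
    B: previous converged V_R as guess  D: dynamic delta = |d rho|

combined as AC, BC, AD, BD (BD being the production default).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .dielectric import DielectricModel
from .grid import (
    GridMismatchError,
    ScalarField,
    UniformGrid,
    VectorField,
    gradient,
    inner_product,
)
from .poisson import PoissonOperator

__all__ = [
    "SCRFConfig",
    "SCRFState",
    "MacroRecord",
    "MacroTrace",
    "SCRFConvergenceError",
    "effective_density",
    "polarization_function",
    "solve_reaction_potential",
    "macro_driver",
]

FOUR_PI = 4.0 * np.pi


@dataclass(frozen=True)
class SCRFConfig:
    """Microiteration controls.

    delta is the convergence threshold on the L2 norm of the
    reaction-potential update; kain_history = 0 disables acceleration
    (plain damped iteration); damping < 1 is only needed for
    pathological permittivity contrasts and defaults to no damping.
    """

    delta: float = 1e-5
    max_microiter: int = 100
    kain_history: int = 5
    damping: float = 1.0

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.max_microiter < 1:
            raise ValueError("max_microiter must be >= 1")
        if self.kain_history < 0:
            raise ValueError("kain_history must be >= 0")
        if not 0.0 < self.damping <= 1.0:
            raise ValueError("damping must be in (0, 1]")


@dataclass
class SCRFState:
    """Converged (or last) solver state: iterate, trace, iteration count."""

    V_R: ScalarField
    update_norms: list[float] = dc_field(default_factory=list)
    converged: bool = False

    @property
    def microiterations(self) -> int:
        return len(self.update_norms)


class SCRFConvergenceError(RuntimeError):
    """Raised when the microiterations do not reach delta; carries the
    last state so the trace can be inspected."""

    def __init__(self, message: str, state: SCRFState):
        super().__init__(message)
        self.state = state


def effective_density(rho: ScalarField, eps: ScalarField) -> ScalarField:
    """Effective charge rho_eff = rho / eps (nodewise)."""
    if rho.grid != eps.grid:
        raise GridMismatchError("rho and eps live on different grids")
    if eps.values.min() <= 0:
        raise ValueError("permittivity must be positive everywhere")
    return ScalarField(rho.grid, rho.values / eps.values)


def polarization_function(grad_log_eps: VectorField, grad_V: VectorField) -> ScalarField:
    """Polarization function gamma = (1/4 pi) grad(log eps) . grad V."""
    return (1.0 / FOUR_PI) * grad_log_eps.dot(grad_V)


def _update_norm(a: np.ndarray, grid: UniformGrid) -> float:
    return float(np.sqrt(np.sum(a * a) * grid.cell_volume))


def solve_reaction_potential(
    rho: ScalarField,
    model: DielectricModel,
    config: SCRFConfig = SCRFConfig(),
    guess: ScalarField | None = None,
    operator: PoissonOperator | None = None,
    precomputed: tuple[ScalarField, VectorField] | None = None,
) -> tuple[ScalarField, SCRFState]:
    """Microiterate the reaction potential for a fixed charge density.

    Parameters
    ----------
    rho:
        Solute charge density (e/bohr^3), decaying at the box faces.
    model:
        Dielectric model; its eps and grad log eps are evaluated on
        rho's grid unless ``precomputed`` supplies them.
    guess:
        Starting reaction potential; zero when omitted.
    operator, precomputed:
        Optional reuse of the Poisson operator and the (eps,
        grad log eps) pair across repeated solves on one grid.

    Returns the converged V_R and the solver state (update-norm trace).
    Raises :class:`SCRFConvergenceError` when max_microiter is exhausted
    and the final update norm is still above delta.
    """
    from .kain import KainAccelerator

    grid = rho.grid
    if precomputed is not None:
        eps, grad_log_eps = precomputed
    else:
        _, eps, grad_log_eps = model.fields(grid)
    op = operator or PoissonOperator(grid)

    rho_eff = effective_density(rho, eps)
    V_rho = op.apply(rho)
    source_static = rho_eff.values - rho.values  # (rho_eff - rho), fixed

    vol_dot = lambda a, b: float(np.dot(a.ravel(), b.ravel()) * grid.cell_volume)
    kain = KainAccelerator(config.kain_history, dot=vol_dot, damping=config.damping)

    vr = np.zeros(grid.shape) if guess is None else guess.values.copy()
    state = SCRFState(V_R=ScalarField(grid, vr))
    homogeneous = model.is_homogeneous
    best_norm = np.inf

    for _ in range(config.max_microiter):
        V_tot = ScalarField(grid, V_rho.values + vr)
        if homogeneous:
            fixed_point = np.zeros(grid.shape)
        else:
            gamma = polarization_function(grad_log_eps, gradient(V_tot))
            fixed_point = op.apply(
                ScalarField(grid, source_static + gamma.values)
            ).values
        update = fixed_point - vr
        vr_next = kain.step(vr, update)
        if not np.isfinite(vr_next).all():
            raise SCRFConvergenceError(
                "NaN/inf in reaction-potential iterate", state
            )
        norm = _update_norm(vr_next - vr, grid)
        vr = vr_next
        state.V_R = ScalarField(grid, vr)
        state.update_norms.append(norm)
        if norm < config.delta:
            state.converged = True
            return state.V_R, state
        best_norm = min(best_norm, norm)
        if norm > 1e8 * best_norm or norm > 1e12:
            raise SCRFConvergenceError(
                f"SCRF iteration is diverging (update norm {norm:.3e} after "
                f"{state.microiterations} microiterations); for large "
                "permittivity contrasts the plain iteration needs damping "
                "or KAIN acceleration",
                state,
            )

    raise SCRFConvergenceError(
        f"SCRF did not converge in {config.max_microiter} microiterations "
        f"(last update norm {state.update_norms[-1]:.3e} > delta "
        f"{config.delta:.3e})",
        state,
    )


def gpe_residual(rho: ScalarField, V_total: ScalarField, eps: ScalarField) -> float:
    """Relative L2 residual of the discretized GPE,
    || div(eps grad V) + 4 pi rho || / || 4 pi rho ||."""
    from .grid import divergence

    gv = gradient(V_total)
    flux = VectorField(V_total.grid, gv.values * eps.values[..., None])
    res = divergence(flux).values + FOUR_PI * rho.values
    return _update_norm(res, rho.grid) / _update_norm(FOUR_PI * rho.values, rho.grid)


# ---------------------------------------------------------------------------
# macroiteration driver

REGIMES = ("AC", "BC", "AD", "BD")


@dataclass(frozen=True)
class MacroRecord:
    """One macroiteration: density-update norm, threshold, microiterations."""

    density_update_norm: float
    delta_used: float
    microiterations: int


@dataclass
class MacroTrace:
    regime: str
    records: list[MacroRecord]
    V_R: ScalarField

    @property
    def total_microiterations(self) -> int:
        return sum(r.microiterations for r in self.records)


def macro_driver(
    densities: list[ScalarField],
    model: DielectricModel,
    regime: str = "BD",
    base_delta: float = 1e-5,
    config: SCRFConfig = SCRFConfig(),
) -> MacroTrace:
    """Run the SCRF once per macroiteration over a converging density
    sequence, emulating the parent self-consistent-field loop.

    Guess mode (first letter): A restarts from zero every macroiteration,
    B reuses the previous converged reaction potential.  Threshold mode
    (second letter): C uses the fixed ``base_delta`` throughout, D uses
    the dynamic threshold delta^[n] = |d rho^[n]| (the density-update
    norm standing in for the orbital-update norm), floored at
    ``base_delta`` so the final solve is never looser than the target.
    The first macroiteration has no parent update to read a threshold
    from, so mode D falls back to ``base_delta`` there — which also makes
    all four regimes coincide on a single-entry sequence.
    """
    if regime not in REGIMES:
        raise ValueError(f"regime must be one of {REGIMES}, got {regime!r}")
    if not densities:
        raise ValueError("need at least one density")
    grid = densities[0].grid
    _, eps, grad_log_eps = model.fields(grid)
    op = PoissonOperator(grid)

    records: list[MacroRecord] = []
    prev_vr: ScalarField | None = None
    prev_rho: ScalarField | None = None
    for n, rho in enumerate(densities):
        drho = rho.norm() if prev_rho is None else (rho - prev_rho).norm()
        if regime[1] == "C" or prev_rho is None:
            delta = base_delta
        else:
            delta = max(drho, base_delta)
        guess = prev_vr if (regime[0] == "B" and prev_vr is not None) else None
        micro_cfg = SCRFConfig(
            delta=delta,
            max_microiter=config.max_microiter,
            kain_history=config.kain_history,
            damping=config.damping,
        )
        try:
            vr, st = solve_reaction_potential(
                rho, model, micro_cfg, guess=guess, operator=op,
                precomputed=(eps, grad_log_eps),
            )
        except SCRFConvergenceError as exc:
            raise SCRFConvergenceError(
                f"macroiteration {n}: {exc}", exc.state
            ) from exc
        records.append(MacroRecord(drho, delta, st.microiterations))
        prev_vr, prev_rho = vr, rho
    return MacroTrace(regime, records, prev_vr)
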