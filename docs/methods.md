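# Methods

This note records the model equations as implemented, the numerical
choices behind them, and what the verification systems do and do not
demonstrate.  Everything quantitative quoted here is computed by the
test suite or by `scripts/acceptance.py` at run time.

## The electrostatic model

The solvent is a structureless dielectric with position-dependent
permittivity ε(r); the solute is a classical charge density ρ(r).  In
Gaussian atomic units the electrostatics is the generalized Poisson
equation (GPE)

    ∇·(ε ∇V) = −4π ρ.

Expanding the divergence and dividing by ε turns this into an ordinary
Poisson equation with two effective sources,

    ∇²V = −4π (ρ_eff + γ),   ρ_eff = ρ/ε,   γ = (1/4π) ∇log ε · ∇V,

and splitting V = V_ρ + V_R (vacuum potential of ρ plus the reaction
potential; ∇²V_ρ = −4πρ exactly) gives the fixed-point equation the
solver iterates:

    V_R = G ∗ [(ρ_eff − ρ) + γ(V_ρ + V_R)],   G = 1/|r − r′|.

Because γ depends on the total potential, the equation is solved by
microiterations; each one assembles V = V_ρ + V_R^(i), evaluates γ,
applies the Coulomb kernel, and takes a KAIN-accelerated update.  The
iteration is linear in ρ, hence V_R(λρ) = λ V_R(ρ) and
E_pol(λρ) = λ² E_pol(ρ) hold to machine precision (asserted in the
suite).  The polarization energy is the linear-response charging work

    E_pol = ½ ⟨ρ, V_R⟩.

The ½ prefactor is fixed by requiring that the sharp-boundary spherical
limit reproduce the Born energy −(1 − 1/ε) q²/2R, which the radial
oracle (below) confirms.

## Cavity and permittivity parametrization

Each atom i carries a sphere of effective radius

    R_i = α R_i^vdW + β σ

with Bondi van der Waals radii by default and one global (α, β, σ)
triple; per-element and per-atom radius overrides are supported.
Defaults: α = 1.1, β = 0.5, σ = 0.2 bohr.  β shifts the boundary
midpoint outward by half its own width, which partially compensates the
inward bias of the diffuse layer (see "sharp-limit behavior").

A sphere's interior indicator is smoothed with the complementary error
function, C_i(r) = ½ erfc(s_i/σ), s_i = |r − c_i| − R_i.  This profile
is C¹-smooth, strictly monotone, reaches the Heaviside step as σ → 0,
and its derivative is a Gaussian of width σ — the natural smoothing for
erf-based boundaries and the one whose closed-form gradient is
cheapest.  Spheres combine by the complement product

    C = 1 − Π_i (1 − C_i),

which equals C_i for one sphere, stays exactly 1 deep inside *any*
sphere (a plain product of interiors would not), and is permutation
invariant.  ∇C is evaluated analytically by the product rule with
prefix/suffix partial products, so no division by a vanishing (1 − C_i)
occurs; at an exact sphere center the radial direction is undefined and
the (anyway exponentially vanishing) contribution is set to zero.

The permittivity interpolates exponentially,

    ε = ε_in exp[(1 − C) ln(ε_out/ε_in)],

with ε_in = 1 inside by default.  The exponential form makes the only
quantity the solver needs, ∇log ε = −ln(ε_out/ε_in) ∇C, exactly
proportional to the analytic cavity gradient; a finite-difference
fallback exists for user-supplied cavity fields.

## Discretization

All fields live on a uniform isotropic Cartesian grid in bohr.  The box
is the bounding box of all cavity spheres plus a padding (default
8 bohr) on every side; the reaction potential decays as 1/r, so padding
controls the open-boundary truncation error.  Gradients are
second-order central differences (one-sided at faces); integrals are
Riemann sums.

**Coulomb operator.**  Free-space convolution with 1/r is done on a
zero-padded (≥ 2N−1 per axis) grid so periodic images cannot alias —
the discrete kernel is exact free-space, not periodic.  Plain
point-sampling of 1/r limits accuracy to ~4·10⁻³; three layers of
quadrature correction make the operator fourth-order accurate on smooth
densities:

1. kernel values for offsets up to 2 cells are replaced by the exact
   cell averages of 1/r (Gauss–Legendre 16³ per cell; the singular cell
   uses the exact cube mean of 1/r, 2.3800773639795536/h), making the
   sum exact for piecewise-constant densities;
2. the leading local midpoint-sampling error, −(π/6) h² ρ(r), is added
   back analytically;
3. the next local term, proportional to h⁴ Δρ with lattice coefficient
   Q4 = 0.056044 (determined once against the closed-form Gaussian
   potential at four cells per width), is added back using a symmetric
   zero-extended 7-point Laplacian.

Measured accuracy against V = erf(r/w)/r: 5·10⁻⁶ relative at spacing
w/4.  The operator is linear and self-adjoint to machine precision, and
the O(N²) direct-sum oracle shares the kernel values so the FFT
machinery can be validated against explicit summation.

**Solute densities.**  Point charges are smeared into normalized
Gaussians, ρ = Σ q_i (πw²)^(−3/2) exp(−|r−r_i|²/w²), default width
w = 0.4 bohr — resolvable at the default spacing 0.2 (the code enforces
w ≥ 2h) while keeping essentially all charge inside a scaled Bondi
sphere.  This classical density stands in for a quantum charge density;
coupling to an actual SCF engine is out of scope and is emulated by the
macro driver below.

## KAIN acceleration

The update f = F(V_R) − V_R of the fixed-point map is mixed over a
short history (default 5) by the Krylov-accelerated inexact Newton
scheme: secant approximations J(x_j − x_n) ≈ f_j − f_n define a small
least-squares system, and the next iterate is the constrained linear
combination x_n + f_n + Σ c_j [(x_j − x_n) + (f_j − f_n)].  For an
exactly linear map on R^d this terminates within d+1 steps — pinned by
a 5-dimensional toy test.  Degenerate secant systems (condition number
> 10¹²) are handled by evicting the oldest history entry and retrying;
with no usable history the step falls back to plain damped mixing.

The plain (history 0, damping 1) iteration is *not* generally
convergent: at ε_out = 80 its spectral radius exceeds one and the
update norm grows without bound.  The solver detects the blow-up and
aborts with the trace; damping ≈ 0.5 restores convergence, and KAIN
needs no damping at all.  This is the practical argument for KAIN being
the default.

## Macroiteration regimes

`macro_driver` emulates the outer SCF loop with a user-supplied
sequence of densities with decreasing update norms.  Two switches give
four regimes: the V_R guess per macroiteration (A: zero, B: previous
converged), and the microiteration threshold (C: fixed base δ,
D: dynamic δ^[n] = ‖Δρ^[n]‖, floored at base δ so the final solve never
runs looser than the target).  The first macroiteration has no parent
update to read, so mode D falls back to base δ there; this also makes
all four regimes coincide on a single-entry sequence.  On a geometric
charging ramp the measured totals order BD ≤ AD ≤ BC ≤ AC, the expected
pattern: a loose threshold saves work early, guess reuse saves work
late.

## Verification systems and oracles

* **Born ion.**  A unit Gaussian charge centered in one sphere.  Two
  independent references: the sharp-cavity closed form
  −(1−1/ε)q²/2R, and the *exact continuum value of the diffuse model*
  from 1-D radial quadrature (`born_diffuse_reference`): by Gauss's
  law the displacement field of a spherically symmetric system is
  D = q_enc/r² regardless of ε(r), so V_R and E_pol reduce to
  one-dimensional integrals evaluated to ~10⁻⁶.
* **Sharp-limit behavior.**  The diffuse model's continuum energy
  approaches Born from above as σ → 0 (for q=1, R=3, ε=80:
  +11.1% at σ=0.4, +5.1% at σ=0.2, +2.4% at σ=0.1, +1.2% at σ=0.05).
  The bias is positive because the exponential interpolation reaches
  ε = √(ε_in ε_out) already at the nominal radius, pulling the
  effective dielectric boundary inward by ≈ 0.7σ; this is precisely
  the bias the default β = 0.5 offsets in molecular cavities.
* **Direct FD solve.**  An independent sparse 7-point flux-form
  discretization of the GPE (geometric face averaging — exact for the
  log-linear ε profile) with Dirichlet boundary values from screened
  multipoles, solved by direct factorization on 32³ grids.  The SCRF
  reaction potential agrees with it to ~5·10⁻³ relative L2 on a
  resolved Born system.
* **Gauss's law.**  The converged γ integrates to the classical induced
  charge −q(1 − 1/ε) within 2% on a resolved Born system.
* **Onsager point dipole.**  Second sharp-limit closed form, available
  as `onsager_reference` for dipolar test systems.

## Resolution requirements and known limitations

* The spacing must resolve *both* the density (w ≥ 2h, enforced) and
  the boundary layer (σ ≳ h, advisory).  The boundary-shell fields
  (∇C, γ) have Gaussian profiles of width σ; sampling them at h > σ
  incurs an aliasing error of order exp(−π²σ²/h²) in the induced
  charge — at σ/h = ½ this is tens of percent, and no fixed-order
  quadrature at fixed h can remove it.  Sub-cell averaging of the
  boundary fields was prototyped and reduced but did not remove the
  error; it was left out to keep the source assembly simple.  This is
  the capability an adaptive multiresolution basis buys and a uniform
  grid deliberately trades away: accuracy here is bought with h, and
  thin boundaries (σ ≤ 0.1 bohr) on large boxes are out of practical
  reach on a uniform grid.
* The discrete 7-point GPE residual of the converged integral-route
  solution is dominated by finite-difference truncation of the narrow
  Gaussian density; it shrinks ~4× per halving of h (second order) but
  carries a large constant (≈ 0.1 relative at w/h = 5, ≈ 0.025 at
  w/h = 10).  It is a consistency diagnostic, not the solver's accuracy
  (energies converge much faster because the residual's dominant part
  is a local discretization artifact orthogonal to the energy).
* The macro driver uses *synthetic* density sequences (charge ramps);
  real SCF density updates change shape as well as norm, so the regime
  comparisons demonstrate the mechanism, not quantitative SCF costs.
* Energies carry O(h²) discretization bias (the Cauchy refinement test
  quantifies it); spacing 0.2 bohr with σ ≥ 0.2 gives energies a few
  percent from the continuum diffuse-model value.
* Only the isotropic dielectric is implemented (no tensor permittivity,
  no nonlocal response); cavities are spheres only (no solvent-excluded
  surfaces or isodensity boundaries); boundaries are open (no periodic
  systems); and no cavitation/dispersion/repulsion terms are included —
  E_pol is the electrostatic component only.
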