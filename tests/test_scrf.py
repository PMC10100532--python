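"""Self-consistent reaction field: sources, microiterations, macro regimes."""

import numpy as np
import pytest

from gpesolv.dielectric import DielectricModel
from gpesolv.grid import ScalarField, UniformGrid, gradient, integrate, inner_product
from gpesolv.poisson import PoissonOperator
from gpesolv.scrf import (
    SCRFConfig,
    SCRFConvergenceError,
    effective_density,
    gpe_residual,
    macro_driver,
    polarization_function,
    solve_reaction_potential,
)
from gpesolv.solvation import (
    born_system,
    build_grid,
    gaussian_density,
    polarization_energy,
)


class TestEffectiveDensity:
    def test_unit_permittivity_is_identity(self, small_grid, rng):
        rho = ScalarField(small_grid, rng.standard_normal(small_grid.shape))
        eps = ScalarField(small_grid, np.ones(small_grid.shape))
        np.testing.assert_array_equal(effective_density(rho, eps).values, rho.values)

    def test_constant_permittivity_scales(self, small_grid, rng):
        rho = ScalarField(small_grid, rng.standard_normal(small_grid.shape))
        eps = ScalarField(small_grid, np.full(small_grid.shape, 4.0))
        np.testing.assert_allclose(effective_density(rho, eps).values, rho.values / 4)

    def test_bounded_between_zero_and_rho(self, small_grid, rng):
        rho = ScalarField(small_grid, np.abs(rng.standard_normal(small_grid.shape)))
        eps = ScalarField(small_grid, rng.uniform(1.0, 80.0, small_grid.shape))
        re = effective_density(rho, eps).values
        assert np.all(re >= 0) and np.all(re <= rho.values + 1e-15)

    def test_nonpositive_eps_rejected(self, small_grid):
        rho = small_grid.zeros()
        eps = ScalarField(small_grid, np.zeros(small_grid.shape))
        with pytest.raises(ValueError):
            effective_density(rho, eps)


class TestPolarizationFunction:
    def test_zero_log_derivative_gives_zero(self, small_grid, rng):
        from gpesolv.grid import VectorField

        zero = VectorField(small_grid, np.zeros((*small_grid.shape, 3)))
        gv = VectorField(small_grid, rng.standard_normal((*small_grid.shape, 3)))
        assert np.abs(polarization_function(zero, gv).values).max() == 0.0

    def test_orthogonal_fields_give_zero(self, small_grid):
        from gpesolv.grid import VectorField

        a = np.zeros((*small_grid.shape, 3))
        b = np.zeros((*small_grid.shape, 3))
        a[..., 0] = 1.0
        b[..., 1] = 2.0
        out = polarization_function(
            VectorField(small_grid, a), VectorField(small_grid, b)
        )
        assert np.abs(out.values).max() == 0.0

    def test_gauss_law_total_induced_charge(self, born_setup, born_solution):
        # for a charge q centered in a spherical cavity the induced
        # (polarization) charge integrates to -q (1 - 1/eps_out)
        mol, cav, grid, rho, model = born_setup
        V_R, _ = born_solution
        _, eps, gle = model.fields(grid)
        V_tot = ScalarField(grid, PoissonOperator(grid).apply(rho).values + V_R.values)
        gamma = polarization_function(gle, gradient(V_tot))
        expected = -1.0 * (1 - 1 / 80.0)
        assert integrate(gamma) == pytest.approx(expected, rel=0.02)


class TestSolveReactionPotential:
    def test_vacuum_limit_one_microiteration(self, born_setup):
        mol, cav, grid, rho, _ = born_setup
        model = DielectricModel(cav, eps_out=1.0, eps_in=1.0)
        V_R, state = solve_reaction_potential(rho, model, SCRFConfig(delta=1e-8))
        assert state.microiterations == 1
        assert np.abs(V_R.values).max() == 0.0

    def test_linear_response_scaling(self, born_setup, born_solution):
        # V_R(lambda rho) = lambda V_R(rho) to high accuracy
        mol, cav, grid, rho, model = born_setup
        V_R, _ = born_solution
        lam = 2.5
        V_R2, _ = solve_reaction_potential(
            ScalarField(grid, lam * rho.values), model, SCRFConfig(delta=1e-6 * lam)
        )
        rel = (V_R2 - lam * V_R).norm() / (lam * V_R).norm()
        assert rel < 1e-4
        e1 = polarization_energy(rho, V_R)
        e2 = polarization_energy(ScalarField(grid, lam * rho.values), V_R2)
        assert e2 / e1 == pytest.approx(lam**2, rel=1e-4)

    def test_polarization_energy_is_negative(self, born_setup, born_solution):
        mol, cav, grid, rho, _ = born_setup
        V_R, _ = born_solution
        assert polarization_energy(rho, V_R) < 0

    def test_guess_independence(self, born_setup, born_solution):
        # zero guess vs a deliberately wrong guess: same converged field
        mol, cav, grid, rho, model = born_setup
        V_R, _ = born_solution
        delta = 1e-6
        bad_guess = ScalarField(grid, 0.5 * V_R.values)
        V_Rb, _ = solve_reaction_potential(
            rho, model, SCRFConfig(delta=delta), guess=bad_guess
        )
        assert (V_Rb - V_R).norm() <= 10 * delta

    def test_gpe_residual_improves_under_refinement(self):
        # the integral-route solution is not an exact FD solution, so its
        # 7-point residual is dominated by FD truncation of the narrow
        # density; it must shrink ~4x per halving and reach a few percent
        mol, cav = born_system(q=1.0, radius=2.0, sigma=0.8, width=1.0)
        residuals = []
        for h in (0.4, 0.2, 0.1):
            grid = build_grid(cav, h, 4.0)
            rho = gaussian_density(mol, grid)
            model = DielectricModel(cav, eps_out=80.0)
            V_R, _ = solve_reaction_potential(rho, model, SCRFConfig(delta=1e-5))
            V_tot = ScalarField(grid, PoissonOperator(grid).apply(rho).values + V_R.values)
            _, eps, _ = model.fields(grid)
            residuals.append(gpe_residual(rho, V_tot, eps))
        assert residuals[0] > residuals[1] > residuals[2]
        assert residuals[0] / residuals[1] > 2.5
        assert residuals[2] < 0.05

    def test_nonconvergence_carries_trace(self, born_setup):
        mol, cav, grid, rho, model = born_setup
        with pytest.raises(SCRFConvergenceError) as exc:
            solve_reaction_potential(rho, model, SCRFConfig(delta=1e-12, max_microiter=2))
        assert exc.value.state.microiterations == 2
        assert len(exc.value.state.update_norms) == 2

    def test_plain_iteration_diverges_at_high_contrast(self, born_setup):
        # undamped Picard iteration is unstable at eps = 80; the solver
        # must detect the blow-up instead of looping to the cap
        mol, cav, grid, rho, model = born_setup
        with pytest.raises(SCRFConvergenceError, match="diverging|did not converge"):
            solve_reaction_potential(
                rho, model, SCRFConfig(delta=1e-6, kain_history=0, max_microiter=60)
            )

    def test_damped_plain_iteration_converges(self, born_setup, born_solution):
        mol, cav, grid, rho, model = born_setup
        V_ref, _ = born_solution
        V_R, state = solve_reaction_potential(
            rho, model,
            SCRFConfig(delta=1e-6, kain_history=0, damping=0.5, max_microiter=100),
        )
        assert state.converged
        assert (V_R - V_ref).norm() / V_ref.norm() < 1e-4


class TestMonotonicity:
    def test_energy_deepens_with_permittivity(self, born_setup):
        # |E_pol| strictly increases along eps_out = 2, 4, 80
        mol, cav, grid, rho, _ = born_setup
        energies = []
        op = PoissonOperator(grid)
        for eo in (2.0, 4.0, 80.0):
            model = DielectricModel(cav, eps_out=eo)
            V_R, _ = solve_reaction_potential(
                rho, model, SCRFConfig(delta=1e-6), operator=op
            )
            energies.append(polarization_energy(rho, V_R))
        assert energies[0] > energies[1] > energies[2]  # all negative, deepening
        assert all(e < 0 for e in energies)


class TestMacroDriver:
    @pytest.fixture(scope="class")
    def macro_setup(self):
        mol, cav = born_system(q=1.0, radius=2.0, sigma=0.4, width=0.6)
        grid = build_grid(cav, 0.3, 5.0)
        rho1 = gaussian_density(mol, grid)
        qs = [1.0 - 0.5 ** (k + 1) for k in range(7)] + [1.0]
        densities = [ScalarField(grid, q * rho1.values) for q in qs]
        model = DielectricModel(cav, eps_out=80.0)
        return densities, model

    def test_single_density_all_regimes_agree(self, macro_setup):
        densities, model = macro_setup
        results = {}
        for regime in ("AC", "BC", "AD", "BD"):
            tr = macro_driver([densities[-1]], model, regime, base_delta=1e-5)
            results[regime] = tr
        ref = results["AC"]
        for regime, tr in results.items():
            assert tr.total_microiterations == ref.total_microiterations
            assert (tr.V_R - ref.V_R).norm() < 1e-12

    def test_dynamic_threshold_floors_at_base_delta(self, macro_setup):
        densities, model = macro_setup
        # constant density sequence: updates are zero, so the dynamic
        # threshold floors immediately and BD coincides with BC
        seq = [densities[-1]] * 3
        bd = macro_driver(seq, model, "BD", base_delta=1e-5)
        bc = macro_driver(seq, model, "BC", base_delta=1e-5)
        assert [r.delta_used for r in bd.records][1:] == [
            r.delta_used for r in bc.records
        ][1:]
        # identical thresholds from macro 1 on -> identical microiteration
        # counts there (macro 0 differs: BD starts from the loose dynamic
        # threshold, BC from base_delta)
        assert [r.microiterations for r in bd.records][1:] == [
            r.microiterations for r in bc.records
        ][1:]

    def test_default_regime_beats_zero_guess_fixed_threshold(self, macro_setup):
        densities, model = macro_setup
        totals = {
            regime: macro_driver(densities, model, regime, base_delta=1e-5).total_microiterations
            for regime in ("AC", "BD")
        }
        assert totals["BD"] <= totals["AC"]

    def test_records_track_thresholds(self, macro_setup):
        densities, model = macro_setup
        tr = macro_driver(densities, model, "AD", base_delta=1e-5)
        assert len(tr.records) == len(densities)
        assert tr.records[0].delta_used == 1e-5  # no parent update yet
        for rec in tr.records[1:]:
            assert rec.delta_used == pytest.approx(max(rec.density_update_norm, 1e-5))

    def test_unknown_regime_rejected(self, macro_setup):
        densities, model = macro_setup
        with pytest.raises(ValueError, match="regime"):
            macro_driver(densities[:1], model, "XX")
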