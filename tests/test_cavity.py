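"""Interlocking-spheres cavity: radii, profile, combination rule, gradient."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gpesolv.cavity import (
    Cavity,
    CavityParams,
    CavitySphere,
    cavity_function,
    cavity_gradient,
    effective_radius,
    signed_distance,
    sphere_boundary,
    sphere_boundary_derivative,
)
from gpesolv.grid import UniformGrid, gradient


def make_cavity(spheres_spec, sigma=0.2):
    params = CavityParams(alpha=1.0, beta=0.0, sigma=sigma)
    spheres = tuple(
        CavitySphere.from_vdw(c, r, params) for c, r in spheres_spec
    )
    return Cavity(spheres, params)


class TestEffectiveRadius:
    def test_default_parameters(self):
        # alpha*R + beta*sigma with the production defaults
        assert effective_radius(2.0, CavityParams(1.1, 0.5, 0.2)) == pytest.approx(2.3)

    def test_beta_zero_scales_only(self):
        # alpha=1.1, beta=0 reproduces the plain scaled-Bondi convention
        assert effective_radius(1.8, CavityParams(1.1, 0.0, 0.2)) == pytest.approx(1.98)

    def test_identity_parameters(self):
        assert effective_radius(2.5, CavityParams(1.0, 0.0, 0.1)) == 2.5

    def test_invalid_radius_rejected(self):
        with pytest.raises(ValueError):
            effective_radius(-1.0, CavityParams())


class TestSignedDistance:
    def test_center_surface_outside(self):
        s = CavitySphere((1.0, 0.0, 0.0), 2.0, 2.0)
        assert signed_distance(np.array([1.0, 0, 0]), s) == pytest.approx(-2.0)
        assert signed_distance(np.array([3.0, 0, 0]), s) == pytest.approx(0.0)
        assert signed_distance(np.array([4.0, 0, 0]), s) == pytest.approx(1.0)


class TestSphereBoundary:
    def test_midpoint_is_half(self):
        assert sphere_boundary(0.0, 0.3) == pytest.approx(0.5)

    def test_deep_tails(self):
        assert sphere_boundary(-6 * 0.2, 0.2) == pytest.approx(1.0, abs=1e-9)
        assert sphere_boundary(+6 * 0.2, 0.2) == pytest.approx(0.0, abs=1e-9)

    @given(st.lists(st.integers(-50, 50), min_size=2, max_size=20, unique=True))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_strictly_decreasing(self, steps):
        # |s|/sigma <= 5: beyond that the erfc tail saturates to exactly
        # 0/1 in double precision and strictness is unobservable
        svals = 0.05 * np.array(sorted(steps), dtype=float)
        c = sphere_boundary(svals, 0.5)
        assert np.all(np.diff(c) < 0)

    def test_derivative_matches_finite_difference(self):
        s = np.linspace(-1, 1, 41)
        h = 1e-6
        fd = (sphere_boundary(s + h, 0.3) - sphere_boundary(s - h, 0.3)) / (2 * h)
        np.testing.assert_allclose(
            sphere_boundary_derivative(s, 0.3), fd, rtol=1e-6, atol=1e-12
        )


class TestCavityFunction:
    def test_single_sphere_equals_profile(self, small_grid):
        cav = make_cavity([((0.0, 0.0, 0.0), 2.0)], sigma=0.3)
        C = cavity_function(small_grid, cav)
        X, Y, Z = small_grid.meshgrid()
        s = np.sqrt(X**2 + Y**2 + Z**2) - 2.0 + np.zeros(small_grid.shape)
        np.testing.assert_allclose(C.values, sphere_boundary(s, 0.3), atol=1e-14)

    def test_far_outside_all_spheres_is_zero(self):
        g = UniformGrid((10.0, 10.0, 10.0), 0.5, (8, 8, 8))
        cav = make_cavity([((0.0, 0.0, 0.0), 1.0)], sigma=0.2)
        assert cavity_function(g, cav).values.max() < 1e-9

    def test_overlapping_spheres_bound_below_by_each_profile(self):
        # complement-product combination: C >= max of the individual C_a
        n, h = 32, 0.25
        g = UniformGrid((-0.5 * h * (n - 1),) * 3, h, (n,) * 3)
        spec = [((-0.8, 0, 0), 1.5), ((0.8, 0.2, 0), 1.4)]
        cav = make_cavity(spec, sigma=0.3)
        C = cavity_function(g, cav).values
        for c, r in spec:
            single = cavity_function(g, make_cavity([(c, r)], sigma=0.3)).values
            assert np.all(C >= single - 1e-12)

    def test_values_within_unit_interval_random_cavities(self, rng):
        g = UniformGrid((-3.0, -3.0, -3.0), 0.5, (13, 13, 13))
        for _ in range(5):
            k = rng.integers(1, 5)
            spec = [
                (tuple(rng.uniform(-2, 2, 3)), rng.uniform(0.5, 2.5))
                for _ in range(k)
            ]
            C = cavity_function(g, make_cavity(spec, sigma=rng.uniform(0.1, 0.6)))
            assert C.values.min() >= 0.0 and C.values.max() <= 1.0

    def test_boundary_width_scales_linearly_with_sigma(self):
        # the 0.01 < C < 0.99 shell narrows ~proportionally when sigma /= 4
        widths = {}
        for sigma in (0.4, 0.1):
            r = np.linspace(1.0, 5.0, 20001)
            c = sphere_boundary(r - 3.0, sigma)
            band = r[(c > 0.01) & (c < 0.99)]
            widths[sigma] = band.max() - band.min()
        assert widths[0.4] / widths[0.1] == pytest.approx(4.0, rel=0.1)

    def test_permutation_invariance(self, small_grid):
        spec = [((-1.0, 0, 0), 1.2), ((1.0, 0.5, 0), 1.6), ((0, -1, 0.5), 0.9)]
        c1 = cavity_function(small_grid, make_cavity(spec)).values
        c2 = cavity_function(small_grid, make_cavity(spec[::-1])).values
        np.testing.assert_allclose(c1, c2, atol=1e-14)


class TestCavityGradient:
    def test_zero_in_constant_regions(self):
        g_in = UniformGrid((-0.5, -0.5, -0.5), 0.125, (9, 9, 9))  # deep inside
        cav = make_cavity([((0.0, 0.0, 0.0), 4.0)], sigma=0.2)
        assert cavity_gradient(g_in, cav).magnitude().values.max() < 1e-12

    def test_surface_magnitude_and_direction(self):
        # |dC/ds| at s=0 is 1/(sigma sqrt(pi)); direction radially inward-
        # pointing gradient (C decreases outward)
        sigma = 0.25
        cav = make_cavity([((0.0, 0.0, 0.0), 2.0)], sigma=sigma)
        g = UniformGrid((1.9, -0.2, -0.2), 0.05, (8, 8, 8))
        gc = cavity_gradient(g, cav)
        X, Y, Z = g.meshgrid(sparse=False)
        r = np.sqrt(X**2 + Y**2 + Z**2)
        iz = np.unravel_index(np.argmin(np.abs(r - 2.0)), r.shape)
        vec = gc.values[iz]
        assert np.linalg.norm(vec) == pytest.approx(1 / (sigma * np.sqrt(np.pi)), rel=1e-3)
        rad = np.array([X[iz], Y[iz], Z[iz]]) / r[iz]
        assert np.dot(vec, rad) < 0  # points inward

    def test_matches_finite_differences_on_molecular_cavity(self):
        # closed-form gradient vs central differences of C: O(h^2) agreement
        spec = [((0.0, 0.0, 0.4), 1.5), ((0.0, 1.4, -0.9), 1.2), ((0.0, -1.4, -0.9), 1.2)]
        errs = []
        for n, h in ((28, 0.25), (56, 0.125)):
            g = UniformGrid((-0.5 * h * (n - 1),) * 3, h, (n,) * 3)
            cav = make_cavity(spec, sigma=0.4)
            exact = cavity_gradient(g, cav).values[2:-2, 2:-2, 2:-2]
            fd = gradient(cavity_function(g, cav)).values[2:-2, 2:-2, 2:-2]
            errs.append(np.abs(exact - fd).max())
        assert errs[0] / errs[1] > 2.5  # shrinks ~4x per halving
        assert errs[1] < 0.05

    def test_sphere_center_contribution_is_finite_zero(self):
        cav = make_cavity([((0.0, 0.0, 0.0), 3.0)], sigma=0.2)
        g = UniformGrid((-0.7, -0.7, -0.7), 0.2, (8, 8, 8))  # includes center
        vals = cavity_gradient(g, cav).values
        assert np.isfinite(vals).all()
        ic = np.argmin(np.abs(g.axes()[0]))
        assert np.linalg.norm(vals[ic, ic, ic]) < 1e-12

    def test_permutation_invariance(self, small_grid):
        spec = [((-1.0, 0, 0), 1.2), ((1.0, 0.5, 0), 1.6), ((0, -1, 0.5), 0.9)]
        g1 = cavity_gradient(small_grid, make_cavity(spec)).values
        g2 = cavity_gradient(small_grid, make_cavity(spec[::-1])).values
        np.testing.assert_allclose(g1, g2, atol=1e-14)
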