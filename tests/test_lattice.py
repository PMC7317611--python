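"""D3Q19 stencil, equilibrium, MRT collision and moments."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemolattice.lattice import (
    UnitSystem,
    build_d3q19,
    deviatoric_stress,
    equilibrium,
    macroscopics,
    mrt_collide,
    tau_from_viscosity,
    viscosity_from_tau,
    wall_shear_stress,
)
from hemolattice.lattice import make_mrt


@pytest.fixture(scope="module")
def lat():
    return build_d3q19()


class TestStencil:
    def test_counts_and_sound_speed(self, lat):
        assert lat.q == 19
        assert lat.cs2 == pytest.approx(1.0 / 3.0)
        norms = np.sort((lat.c**2).sum(axis=1))
        assert (norms == np.sort([0] + [1] * 6 + [2] * 12)).all()

    def test_isotropy_identities(self, lat):
        assert lat.w.sum() == pytest.approx(1.0)
        assert np.allclose((lat.w[:, None] * lat.c).sum(axis=0), 0.0)
        second = np.einsum("i,ia,ib->ab", lat.w, *(lat.c.astype(float),) * 2)
        assert np.allclose(second, np.eye(3) / 3.0, atol=1e-15)

    def test_every_direction_has_an_opposite(self, lat):
        assert np.array_equal(lat.c[lat.opposite], -lat.c)
        assert np.array_equal(lat.opposite[lat.opposite], np.arange(19))


class TestEquilibrium:
    def test_rest_state_is_the_weights(self, lat):
        assert np.allclose(equilibrium(1.0, np.zeros(3), lat), lat.w)

    @given(
        rho=st.floats(0.5, 2.0),
        ux=st.floats(-0.1, 0.1),
        uy=st.floats(-0.1, 0.1),
        uz=st.floats(-0.1, 0.1),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_moments_exact(self, lat, rho, ux, uy, uz):
        u = np.array([ux, uy, uz])
        feq = equilibrium(rho, u, lat)
        assert feq.sum() == pytest.approx(rho, rel=1e-12)
        assert np.allclose(feq @ lat.c.astype(float), rho * u, atol=1e-14)

    def test_rest_direction_matches_term_by_term_expansion(self, lat):
        # independent brute-force evaluation of the second-order polynomial
        u = np.array([0.1, 0.0, 0.0])
        feq = equilibrium(1.0, u, lat)
        w0 = 1.0 / 3.0
        cu = 0.0
        expected = w0 * (1 + 3 * cu + 4.5 * cu**2 - 1.5 * (0.1**2))
        assert feq[0] == pytest.approx(expected, rel=1e-14)

    def test_rejects_bad_inputs(self, lat):
        with pytest.raises(ValueError):
            equilibrium(-1.0, np.zeros(3), lat)
        with pytest.raises(ValueError):
            equilibrium(1.0, np.array([np.nan, 0, 0]), lat)


class TestMRT:
    def test_moment_matrix_invertible(self, lat):
        op = make_mrt(0.8, lat)
        assert np.allclose(op.M @ op.Minv, np.eye(19), atol=1e-12)

    def test_conserved_moments_not_relaxed(self, lat):
        op = make_mrt(0.8, lat)
        assert op.S[0] == 0.0 and op.S[3] == 0.0
        assert op.S[5] == 0.0 and op.S[7] == 0.0

    def test_equilibrium_is_a_fixed_point(self, lat):
        op = make_mrt(0.7, lat)
        f = equilibrium(1.1, np.array([0.03, -0.02, 0.01]), lat)
        assert np.allclose(mrt_collide(f, op), f, atol=1e-14)

    def test_collision_conserves_mass_and_momentum(self, lat):
        rng = np.random.default_rng(7)
        op = make_mrt(0.62, lat)
        f = equilibrium(1.0, np.array([0.05, 0.0, 0.02]), lat)
        f = f * (1 + 0.05 * rng.standard_normal(19))
        fc = mrt_collide(f, op)
        assert fc.sum() == pytest.approx(f.sum(), rel=1e-13)
        assert np.allclose(
            fc @ lat.c.astype(float), f @ lat.c.astype(float), atol=1e-15
        )

    def test_uniform_rates_reproduce_bgk(self, lat):
        """MRT with S = (1/tau) I equals the direct BGK update."""
        rng = np.random.default_rng(3)
        tau = 0.8
        op = make_mrt(tau, lat, uniform=True)
        for _ in range(5):
            f = equilibrium(1.0, 0.1 * rng.uniform(-1, 1, 3), lat)
            f = f * (1 + 0.02 * rng.standard_normal(19))
            rho, u, _ = macroscopics(f, lat)
            bgk = f - (f - equilibrium(rho, u, lat)) / tau
            assert np.allclose(mrt_collide(f, op), bgk, atol=1e-15)

    def test_tau_must_exceed_half(self, lat):
        with pytest.raises(ValueError):
            make_mrt(0.5, lat)


class TestMacroscopics:
    def test_rest_state(self, lat):
        rho, u, p = macroscopics(lat.w, lat)
        assert rho == pytest.approx(1.0)
        assert np.allclose(u, 0.0)
        assert p == pytest.approx(1.0 / 3.0)

    def test_equilibrium_moments_round_trip(self, lat):
        f = equilibrium(1.2, np.array([0.05, 0, 0]), lat)
        rho, u, p = macroscopics(f, lat)
        assert rho == pytest.approx(1.2, rel=1e-13)
        assert u[0] == pytest.approx(0.05, rel=1e-12)
        assert p == pytest.approx(0.4, rel=1e-13)

    def test_matches_brute_force_summation(self, lat):
        rng = np.random.default_rng(11)
        f = rng.uniform(0.01, 0.1, 19)
        rho, u, p = macroscopics(f, lat)
        rho_bf = sum(f[i] for i in range(19))
        u_bf = sum(f[i] * lat.c[i] for i in range(19)) / rho_bf
        assert rho == pytest.approx(rho_bf, rel=1e-14)
        assert np.allclose(u, u_bf, rtol=1e-13)
        assert p == pytest.approx(rho_bf / 3.0)

    def test_blowup_detected(self, lat):
        f = -np.abs(np.random.default_rng(0).uniform(size=19))
        with pytest.raises(FloatingPointError):
            macroscopics(f, lat)


class TestUnits:
    def test_tau_viscosity_closed_form(self):
        assert tau_from_viscosity(1.0 / 6.0) == pytest.approx(1.0)
        # substituting the shipped minimum lattice viscosity
        assert tau_from_viscosity(1.0e-3) == pytest.approx(0.503)
        assert viscosity_from_tau(tau_from_viscosity(0.004)) == pytest.approx(
            0.004
        )

    def test_tau_decreases_towards_half(self):
        taus = [tau_from_viscosity(nu) for nu in (1e-1, 1e-2, 1e-3, 1e-5)]
        assert all(a > b for a, b in zip(taus, taus[1:]))
        assert taus[-1] > 0.5

    def test_round_trip_conversions(self):
        u = UnitSystem.from_density(1e-4, 1e-5, 1000.0)
        assert u.dm == pytest.approx(1e-9)  # rho dx^3
        v = 0.37
        assert u.to_physical_velocity(u.to_lattice_velocity(v)) == (
            pytest.approx(v, rel=1e-15)
        )

    def test_positivity_enforced(self):
        with pytest.raises(ValueError):
            UnitSystem(dx=-1e-4, dt=1e-5, dm=1e-9)


class TestWallShearStress:
    def test_zero_for_equilibrium(self, lat):
        op = make_mrt(0.8, lat)
        units = UnitSystem.from_density(1e-4, 1e-5, 1000.0)
        f = equilibrium(1.0, np.array([0.05, 0, 0]), lat)
        wss = wall_shear_stress(
            f[None, :], op, units, np.array([[0.0, 1.0, 0.0]])
        )
        assert wss[0] == pytest.approx(0.0, abs=1e-12)

    def test_linear_shear_recovers_analytic_stress(self, lat):
        """Chapman-Enskog f for a pure shear gives tau = mu du/dy exactly.

        The first-order distribution for strain rate S is
        ``f1 = -w tau rho / cs^2 (c c - cs^2 I) : S``; feeding
        ``f = feq + f1`` through the moment-based extraction must return
        ``mu |du/dy|`` in physical units (a plane-channel wall sees exactly
        this local state).
        """
        tau = 0.8
        op = make_mrt(tau, lat)
        units = UnitSystem.from_density(1e-4, 2e-5, 1000.0)
        dudy = 0.01  # lattice units, du_x/dy
        S = np.zeros((3, 3))
        S[0, 1] = S[1, 0] = 0.5 * dudy
        c = lat.c.astype(float)
        cc = np.einsum("ia,ib->iab", c, c) - np.eye(3) / 3.0
        f1 = -lat.w * tau * 3.0 * np.einsum("iab,ab->i", cc, S)
        f = equilibrium(1.0, np.zeros(3), lat) + f1
        wss = wall_shear_stress(
            f[None, :], op, units, np.array([[0.0, 1.0, 0.0]])
        )
        nu_lbm = viscosity_from_tau(tau)
        mu_phys = 1.0 * nu_lbm * units.density * units.kinematic_viscosity
        expected = mu_phys * dudy * units.velocity / units.dx
        assert wss[0] == pytest.approx(expected, rel=1e-10)

    def test_rotation_invariance(self, lat):
        """Rotating the shear plane by 90 deg leaves the magnitude."""
        tau = 0.7
        op = make_mrt(tau, lat)
        units = UnitSystem.from_density(1e-4, 2e-5, 1000.0)
        c = lat.c.astype(float)
        cc = np.einsum("ia,ib->iab", c, c) - np.eye(3) / 3.0

        def wss_for(axis_u, axis_n):
            S = np.zeros((3, 3))
            S[axis_u, axis_n] = S[axis_n, axis_u] = 0.005
            f1 = -lat.w * tau * 3.0 * np.einsum("iab,ab->i", cc, S)
            f = equilibrium(1.0, np.zeros(3), lat) + f1
            n = np.zeros(3)
            n[axis_n] = 1.0
            return wall_shear_stress(f[None, :], op, units, n[None, :])[0]

        vals = [wss_for(0, 1), wss_for(1, 2), wss_for(2, 0)]
        assert np.allclose(vals, vals[0], rtol=1e-12)

    def test_deviatoric_stress_is_traceless(self, lat):
        op = make_mrt(0.9, lat)
        rng = np.random.default_rng(5)
        f = equilibrium(1.0, np.array([0.02, 0.01, 0.0]), lat)
        f = f * (1 + 0.03 * rng.standard_normal(19))
        sig = deviatoric_stress(f, op)
        assert np.trace(sig) == pytest.approx(0.0, abs=1e-14)
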