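"""Interpolated bounce-back, outlet extrapolation and inlet waveforms."""

import numpy as np
import pytest

from hemolattice import _kernels
from hemolattice.boundaries import (
    BoundaryLink,
    Waveform,
    inlet_velocity,
    interpolated_bounce_back,
    neq_extrapolation_outlet,
)
from hemolattice.fixtures import sealed_box_grid
from hemolattice.lattice import (
    UnitSystem,
    build_d3q19,
    equilibrium,
    make_mrt,
)
from hemolattice.state import build_state


@pytest.fixture(scope="module")
def lat():
    return build_d3q19()


class TestBouzidi:
    def test_branch_continuity_at_half(self, lat):
        """Both branch formulas give plain bounce-back at q = 1/2, u_w = 0."""
        rng = np.random.default_rng(0)
        fc = rng.uniform(0.01, 0.1, 19)
        up = rng.uniform(0.01, 0.1, 19)
        for i in range(1, 19):
            lo = interpolated_bounce_back(
                BoundaryLink(node=0, direction=i, q=0.5 - 1e-12), fc, up, lat
            )
            hi = interpolated_bounce_back(
                BoundaryLink(node=0, direction=i, q=0.5), fc, up, lat
            )
            assert lo == pytest.approx(fc[i], rel=1e-9)
            assert hi == pytest.approx(fc[i], rel=1e-12)

    def test_moving_wall_term_continuous_and_signed(self, lat):
        u_w = np.array([0.0, 0.0, 0.02])
        i = int(np.flatnonzero((lat.c == [0, 0, -1]).all(axis=1))[0])
        fc = np.full(19, 0.05)
        vals = [
            interpolated_bounce_back(
                BoundaryLink(node=0, direction=i, q=q, tag="inlet", u_w=u_w),
                fc, fc, lat,
            )
            for q in (0.49999, 0.5, 0.50001)
        ]
        # reflected direction is +z = into the flow: inflow enhances it
        assert vals[1] > fc[i]
        assert vals[0] == pytest.approx(vals[2], rel=1e-3)

    def test_q_fallback_without_upstream(self, lat):
        link = BoundaryLink(node=0, direction=2, q=0.2)
        fc = np.random.default_rng(1).uniform(0.01, 0.1, 19)
        assert interpolated_bounce_back(link, fc, None, lat) == pytest.approx(
            fc[2]
        )

    def test_kernel_matches_reference_formula(self, lat):
        """The compiled streaming path reproduces the single-link formula."""
        rng = np.random.default_rng(2)
        grid = sealed_box_grid(4, 1e-4)
        units = UnitSystem.from_density(1e-4, 1e-5, 1000.0)
        state = build_state(grid, units, lat)
        fc = np.ascontiguousarray(
            rng.uniform(0.01, 0.1, (state.n_fluid, 19))
        )
        fnew = np.zeros_like(fc)
        _kernels.stream(
            fc, fnew, state.srcidx, lat.opposite.astype(np.int64),
            state.qlink, state.ibb_coef, state.ibb_inlet, np.zeros(1),
            state.n_active,
        )
        # check every cut link against the reference implementation
        checked = 0
        for n in range(state.n_active):
            for i in range(1, 19):
                if state.srcidx[n, i] >= 0:
                    continue
                j = int(lat.opposite[i])
                link = BoundaryLink(node=n, direction=j, q=state.qlink[n, j])
                up = state.srcidx[n, j]
                ref = interpolated_bounce_back(
                    link, fc[n], fc[up] if up >= 0 else None, lat
                )
                assert fnew[n, i] == pytest.approx(ref, rel=1e-12)
                checked += 1
        assert checked > 100

    def test_sealed_box_conserves_mass_and_damps_momentum(self, lat):
        """Closed box with resting walls: mass exact, momentum decays."""
        rng = np.random.default_rng(3)
        grid = sealed_box_grid(8, 1e-4)
        units = UnitSystem.from_density(1e-4, 1e-5, 1000.0)
        state = build_state(grid, units, lat)
        n = state.n_fluid
        u0 = 0.02 * rng.uniform(-1, 1, (n, 3))
        rho0 = 1.0 + 0.01 * rng.uniform(-1, 1, n)
        f = equilibrium(rho0, u0, lat)
        op = make_mrt(0.55, lat)
        om = op.omega
        A = np.ascontiguousarray(np.eye(19) - om)
        B = np.ascontiguousarray(om)
        c = lat.c.astype(float)
        cx, cy, cz = c[:, 0].copy(), c[:, 1].copy(), c[:, 2].copy()
        w = lat.w.copy()
        opp = lat.opposite.astype(np.int64)
        fc = np.empty_like(f)
        fn = np.empty_like(f)
        mass0 = f.sum()
        mom = [np.linalg.norm(f @ c)]
        for step in range(1000):
            _kernels.collide(f, fc, A, B, cx, cy, cz, w, n)
            _kernels.stream(
                fc, fn, state.srcidx, opp, state.qlink, state.ibb_coef,
                state.ibb_inlet, np.zeros(1), state.n_active,
            )
            f, fn = fn, f
            if step % 100 == 99:
                mom.append(np.linalg.norm(f @ c))
        assert abs(f.sum() - mass0) / mass0 <= 1e-10
        assert mom[-1] < 0.2 * mom[0]
        assert all(b <= a * 1.01 for a, b in zip(mom, mom[1:]))


class TestOutlet:
    def test_equilibrium_neighbour_gives_equilibrium(self, lat):
        op = make_mrt(0.8, lat)
        u = np.array([0.03, 0.0, 0.01])
        f_nb = equilibrium(1.05, u, lat)
        out = neq_extrapolation_outlet(f_nb, op, p_target_lbm=0.0)
        assert np.allclose(out, equilibrium(1.0, u, lat), atol=1e-14)

    def test_identity_at_rest_target(self, lat):
        op = make_mrt(0.8, lat)
        f_nb = equilibrium(1.0, np.zeros(3), lat)
        out = neq_extrapolation_outlet(f_nb, op)
        assert np.allclose(out, f_nb, atol=1e-15)

    def test_nonequilibrium_part_transferred(self, lat):
        op = make_mrt(0.7, lat)
        rng = np.random.default_rng(4)
        f_nb = equilibrium(1.0, np.array([0.02, 0, 0]), lat)
        f_nb = f_nb + 1e-3 * rng.standard_normal(19)
        out = neq_extrapolation_outlet(f_nb, op)
        # zeroth/first moments follow the target density and neighbour u
        rho_nb = f_nb.sum()
        u_nb = (f_nb @ lat.c.astype(float)) / rho_nb
        # the result carries (I - Omega) f_neq on top of equilibrium
        resid = out - equilibrium(1.0, u_nb, lat)
        expected = (np.eye(19) - op.omega) @ (
            f_nb - equilibrium(rho_nb, u_nb, lat)
        )
        assert np.allclose(resid, expected, atol=1e-14)


class TestWaveform:
    def test_samples_returned_exactly(self):
        t = np.array([0.0, 0.2, 0.4, 0.55, 0.7, 0.9])
        q = np.array([1.0, 4.0, 2.5, 2.0, 1.5, 1.2])
        wf = Waveform(times=t, flow_mlps=q, period=1.0)
        assert np.allclose(wf.flow(t) * 1e6, q)

    def test_periodic_continuation(self):
        wf = Waveform.constant(5.0, period=0.8)
        assert wf.flow(0.3) == pytest.approx(wf.flow(0.3 + 0.8))
        assert wf.flow(-0.5) == pytest.approx(wf.flow(0.3))

    def test_sparse_sampling_warns(self):
        with pytest.warns(UserWarning, match="sample gap"):
            Waveform(
                times=np.array([0.0, 0.5]),
                flow_mlps=np.array([1.0, 2.0]),
                period=1.0,
            )

    def test_csv_round_trip(self, tmp_path):
        from hemolattice.fixtures import default_waveform_samples

        t, q = default_waveform_samples(mean_mlps=5.13, period=1.0)
        wf = Waveform(times=t, flow_mlps=q, period=1.0)
        path = tmp_path / "wave.csv"
        wf.to_csv(path)
        back = Waveform.from_csv(path)
        assert back.period == pytest.approx(1.0)
        assert np.allclose(back.flow_mlps, wf.flow_mlps)


class TestInletVelocity:
    def test_zero_flow_is_zero(self):
        wf = Waveform.constant(0.0, period=1.0)
        u = inlet_velocity(wf, 0.1, 1e-5, np.array([0, 0, 1.0]))
        assert np.allclose(u, 0.0)

    def test_mean_speed_arithmetic(self):
        # 5.13 ml/s through 20 mm^2 -> 256.5 mm/s
        wf = Waveform.constant(5.13, period=1.0)
        u = inlet_velocity(wf, 0.0, 20e-6, np.array([0, 0, 1.0]))
        assert u[2] == pytest.approx(0.2565, rel=1e-12)

    def test_integral_recovers_mean_flow(self):
        from hemolattice.fixtures import default_waveform_samples

        t, q = default_waveform_samples(mean_mlps=5.13, period=1.0, n=256)
        wf = Waveform(times=t, flow_mlps=q, period=1.0)
        area = 2.3e-5
        tt = np.linspace(0, 1.0, 20001)
        u = np.array(
            [inlet_velocity(wf, x, area, np.array([0, 0, 1.0]))[2] for x in tt]
        )
        mean_flow = np.trapezoid(u, tt) * area
        assert mean_flow == pytest.approx(wf.mean_flow(), rel=1e-3)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            inlet_velocity(
                Waveform.constant(1.0, period=1.0), 0.0, 0.0,
                np.array([0, 0, 1.0]),
            )
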