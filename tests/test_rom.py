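"""Centerline extraction and the 1D reduced-order flow model."""

import numpy as np
import pytest

from hemolattice import rom
from hemolattice.boundaries import Waveform
from hemolattice.fixtures import (
    make_bifurcation,
    make_stenosed_tube,
    make_tube,
)

NU, RHO = 4.0e-6, 1000.0
R, L = 2e-3, 12e-3


@pytest.fixture(scope="module")
def tube_net():
    return rom.extract_network(make_tube(R, L, facets=48))


@pytest.fixture(scope="module")
def straight_net():
    """Hand-built single-segment network (no extraction error)."""
    n = 60
    pts = np.column_stack([np.zeros(n), np.zeros(n), np.linspace(0, L, n)])
    seg = rom.Segment1D(
        points=pts,
        r0=np.full(n, R),
        A0=np.full(n, np.pi * R**2),
        parent=-1,
        outlet=0,
    )
    return rom.VesselNetwork1D(segments=[seg])


@pytest.fixture(scope="module")
def bifurcation_net():
    mesh = make_bifurcation(2e-3, 1.5e-3)
    return rom.extract_network(mesh)


class TestExtraction:
    def test_straight_tube_single_segment_area(self, tube_net):
        assert len(tube_net.segments) == 1
        seg = tube_net.segments[0]
        interior = slice(3, -3)
        assert np.allclose(
            seg.A0[interior], np.pi * R**2, rtol=0.02
        )
        assert np.allclose(seg.r0[interior], R, rtol=0.02)

    def test_stenosis_minimum_area_at_constriction(self):
        mesh = make_stenosed_tube(R, 16e-3, severity=0.5, facets=48)
        net = rom.extract_network(mesh)
        seg = net.segments[0]
        k = int(np.argmin(seg.A0))
        assert seg.A0[k] == pytest.approx(0.25 * np.pi * R**2, rel=0.08)
        # the constriction sits at mid-tube (z = 8 mm of 16 mm)
        assert abs(seg.points[k][2] - 8e-3) < 2e-3
        assert net.min_diameter() == pytest.approx(2 * R * 0.5, rel=0.05)

    def test_symmetric_bifurcation_topology(self, bifurcation_net):
        net = bifurcation_net
        assert len(net.segments) == 3
        kids = net.children
        assert list(kids.keys()) == [0]
        a, b = kids[0]
        # compare distal halves (slices near the junction are oblique)
        da = net.segments[a].A0
        db = net.segments[b].A0
        med_a = np.median(da[len(da) // 2:])
        med_b = np.median(db[len(db) // 2:])
        assert med_a == pytest.approx(med_b, rel=0.1)


class TestSolve1D:
    def test_zero_inflow_stays_at_rest(self, straight_net):
        wf = Waveform.constant(0.0, period=0.1)
        sol = rom.solve_1d(straight_net, wf, nu=NU, rho=RHO, cycles=1)
        assert np.allclose(sol.q, 0.0, atol=1e-20)
        assert np.allclose(sol.p, 0.0, atol=1e-12)

    def test_steady_pressure_drop_matches_poiseuille(self, straight_net):
        Q = 0.01 * np.pi * R**2
        wf = Waveform.constant(Q * 1e6, period=0.2)
        sol = rom.solve_1d(straight_net, wf, nu=NU, rho=RHO, cycles=3)
        # interior gradient avoids the characteristic boundary cells
        ncell = sol.p.shape[1]
        i0, i1 = 3, ncell - 4
        dz = sol.cell_x[i1] - sol.cell_x[i0]
        dp = sol.p[-1, i0] - sol.p[-1, i1]
        expected = 8 * RHO * NU * dz * Q / (np.pi * R**4)
        assert dp == pytest.approx(expected, rel=0.02)
        assert np.allclose(sol.q[-1], Q, rtol=1e-4)

    def test_symmetric_bifurcation_splits_evenly(self):
        # hand-built symmetric Y to avoid extraction asymmetry
        n = 40
        z = np.linspace(0, 8e-3, n)
        trunk = rom.Segment1D(
            points=np.column_stack([np.zeros(n), np.zeros(n), z]),
            r0=np.full(n, R), A0=np.full(n, np.pi * R**2), parent=-1,
        )
        def daughter(sign):
            x = sign * np.linspace(0, 5e-3, n)
            zz = 8e-3 + np.linspace(0, 7e-3, n)
            return rom.Segment1D(
                points=np.column_stack([x, np.zeros(n), zz]),
                r0=np.full(n, 0.75 * R),
                A0=np.full(n, np.pi * (0.75 * R) ** 2),
                parent=0, outlet=int(sign > 0),
            )
        net = rom.VesselNetwork1D(segments=[trunk, daughter(1), daughter(-1)])
        Q = 2e-6
        wf = Waveform.constant(Q * 1e6, period=0.1)
        sol = rom.solve_1d(net, wf, nu=NU, rho=RHO, cycles=2)
        q1 = sol.q[-1, sol.seg_slices[1]].mean()
        q2 = sol.q[-1, sol.seg_slices[2]].mean()
        assert q1 == pytest.approx(q2, rel=1e-10)
        assert q1 + q2 == pytest.approx(Q, rel=1e-3)

    def test_rigid_regime_saturates_in_stiffness(self, straight_net):
        Q = 0.01 * np.pi * R**2
        wf = Waveform.constant(Q * 1e6, period=0.2)
        sol1 = rom.solve_1d(straight_net, wf, nu=NU, rho=RHO, cycles=3)
        stiff = rom.VesselNetwork1D(
            segments=straight_net.segments,
            E=2 * straight_net.E,
            h=straight_net.h,
        )
        sol2 = rom.solve_1d(stiff, wf, nu=NU, rho=RHO, cycles=3)
        dp1 = sol1.p[-1, 3] - sol1.p[-1, -4]
        dp2 = sol2.p[-1, 3] - sol2.p[-1, -4]
        assert dp2 == pytest.approx(dp1, rel=0.005)

    def test_mass_conservation_along_segment(self, straight_net):
        from hemolattice.fixtures import default_waveform_samples

        t, q = default_waveform_samples(mean_mlps=2.0, period=0.2, n=64)
        wf = Waveform(times=t, flow_mlps=q, period=0.2)
        sol = rom.solve_1d(straight_net, wf, nu=NU, rho=RHO, cycles=3)
        qbar = sol.q.mean(axis=0)
        assert np.all(
            np.abs(qbar[2:-2] - qbar[2:-2].mean())
            <= 0.005 * abs(qbar[2:-2].mean())
        )


class TestUmax:
    def test_steady_arithmetic(self, straight_net):
        sol = rom.Solution1D(
            network=straight_net,
            times=np.array([0.0]),
            q=np.full((1, 4), 1e-6),
            p=np.zeros((1, 4)),
            A=np.full((1, 4), 2e-5),
            seg_slices=[slice(0, 4)],
            cell_x=np.linspace(0, L, 4),
        )
        assert rom.estimate_umax(sol) == pytest.approx(0.1)

    def test_localizes_at_minimum_area(self):
        A = np.array([[2e-5, 1e-5, 2e-5]])
        sol = rom.Solution1D(
            network=None, times=np.array([0.0]),
            q=np.full((1, 3), 1e-6), p=np.zeros((1, 3)), A=A,
            seg_slices=[slice(0, 3)], cell_x=np.arange(3.0),
        )
        assert rom.estimate_umax(sol) == pytest.approx(2e-6 / 1e-5)

    def test_pulsatile_peak_at_systole(self, straight_net):
        from hemolattice.fixtures import default_waveform_samples

        t, q = default_waveform_samples(mean_mlps=2.0, period=0.2, n=64)
        wf = Waveform(times=t, flow_mlps=q, period=0.2)
        sol = rom.solve_1d(straight_net, wf, nu=NU, rho=RHO, cycles=3)
        umax = rom.estimate_umax(sol)
        q_peak = wf.flow(np.linspace(0, 0.2, 512)).max()
        assert umax == pytest.approx(
            2 * q_peak / (np.pi * R**2), rel=0.05
        )
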