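"""Shared fixtures.

The expensive 3D solver runs (steady Poiseuille pipe, pulsatile Womersley
pipe) are session-scoped and reused by several tests; everything is
generated programmatically at test time.
"""

import numpy as np
import pytest

from hemolattice.boundaries import Waveform
from hemolattice.engine import SimulationConfig, run
from hemolattice.fixtures import (
    default_waveform_samples,
    make_tube,
    womersley_pipe,
)
from hemolattice.lattice import build_d3q19
from hemolattice.voxelize import TaggedSurfaceMesh, label_nodes, voxelize

TUBE_R = 2e-3
TUBE_L = 12e-3
NU = 4.0e-6
RHO = 1000.0


@pytest.fixture(scope="session")
def lattice():
    return build_d3q19()


@pytest.fixture(scope="session")
def tube_mesh():
    return make_tube(TUBE_R, TUBE_L, facets=48)


@pytest.fixture(scope="session")
def labeled_tube(tube_mesh):
    grid = voxelize(tube_mesh, 2 * TUBE_R / 15)
    return label_nodes(grid, mesh=tube_mesh)


@pytest.fixture(scope="session")
def poiseuille_case():
    """Steady pipe at 15 nodes/diameter via the full automated pipeline.

    The lateral wall carries the aneurysm-dome tag so the dome-averaged
    wall shear stress can be checked against the analytic value.
    """
    mesh = make_tube(TUBE_R, TUBE_L, facets=96)
    tags = mesh.face_tags.copy()
    tags[tags == "wall"] = "dome"
    mesh = TaggedSurfaceMesh(
        vertices=mesh.vertices, faces=mesh.faces, face_tags=tags
    )
    u_mean = 0.01  # m/s -> Re = 20
    Q = u_mean * np.pi * TUBE_R**2
    wf = Waveform.constant(Q * 1e6, period=0.2)
    cfg = SimulationConfig(
        waveform=wf,
        cycles=10,
        steady_tol=1e-8,
        ramp_time=0.02,
        min_nodes=15,
        monitor_every=500,
    )
    result = run(mesh, cfg)
    return {
        "result": result,
        "mesh": mesh,
        "R": TUBE_R,
        "L": TUBE_L,
        "Q": Q,
        "u_mean": u_mean,
        "mu": NU * RHO,
    }


@pytest.fixture(scope="session")
def womersley_case():
    """Two-harmonic pulsatile pipe with a mid-tube profile recording."""
    R, L = TUBE_R, 16e-3
    mesh = make_tube(R, L, facets=64)
    T = 0.2
    Q0 = 0.01 * np.pi * R**2
    t, q = default_waveform_samples(mean_mlps=Q0 * 1e6, period=T, n=64)
    wf = Waveform(times=t, flow_mlps=q, period=T)
    om = 2 * np.pi / T
    harmonics = [
        (0.0, Q0),
        (om, -0.5j * Q0),
        (2 * om, 0.2 * Q0 * np.exp(-1j * np.pi / 6)),
    ]
    analytic = womersley_pipe(R, harmonics, nu=NU, rho=RHO)
    zprobe = 11e-3

    def selector(state):
        pos = state.positions()
        return np.flatnonzero(np.abs(pos[:, 2] - zprobe) < state.units.dx / 2)

    cfg = SimulationConfig(
        waveform=wf,
        cycles=3,
        ramp_time=0.02,
        min_nodes=15,
        monitor_every=500,
        record_selector=selector,
        record_every=25,
    )
    result = run(mesh, cfg)
    return {"result": result, "analytic": analytic, "R": R}
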