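"""Boundary condition models.

Walls and velocity inlets use the interpolated (Bouzidi-type) bounce-back,
which places the vessel surface at the sub-grid fraction ``q`` along each
cut lattice link; pressure outlets use the non-equilibrium extrapolation
method, replacing all distributions at the outflow node from an interior
neighbour.  The inlet waveform is a periodic flow-rate time series applied
as a flat (plug) velocity profile over the inlet plane.

The functions here are the single-link reference implementations; the
production time loop applies the same formulas in the compiled kernels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lattice import Lattice, MRTOperator, build_d3q19, equilibrium

__all__ = [
    "Waveform",
    "BoundaryLink",
    "interpolated_bounce_back",
    "neq_extrapolation_outlet",
    "inlet_velocity",
]


@dataclass
class Waveform:
    """Periodic inlet flow-rate waveform.

    ``times`` [s] must start at 0 and stay below ``period``; ``flow_mlps``
    holds samples in ml/s.  Evaluation wraps periodically and interpolates
    linearly, returning exactly the sample values at sample times.
    """

    times: np.ndarray
    flow_mlps: np.ndarray
    period: float

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.flow_mlps = np.asarray(self.flow_mlps, dtype=float)
        if self.period <= 0:
            raise ValueError("period must be positive")
        if np.any(np.diff(self.times) <= 0) or self.times[0] < 0:
            raise ValueError("times must be strictly increasing and >= 0")
        if self.times[-1] >= self.period:
            raise ValueError("times must stay below one period")
        gaps = np.diff(np.r_[self.times, self.times[0] + self.period])
        if np.max(gaps) > self.period / 16:
            import warnings

            warnings.warn(
                "waveform sample gap exceeds period/16; interpolation may "
                "be inaccurate",
                stacklevel=2,
            )

    @classmethod
    def constant(cls, q_mlps: float, period: float = 1.0, n: int = 32):
        t = np.linspace(0, period, n, endpoint=False)
        return cls(times=t, flow_mlps=np.full(n, q_mlps), period=period)

    @classmethod
    def from_csv(cls, path, period: float | None = None):
        """Two-column CSV: time [s], flow rate [ml/s]."""
        data = np.loadtxt(path, delimiter=",", comments="#")
        t, q = data[:, 0], data[:, 1]
        if period is None:
            # assume samples span one period with uniform spacing
            period = t[-1] + (t[-1] - t[-2])
        return cls(times=t, flow_mlps=q, period=period)

    def to_csv(self, path):
        np.savetxt(
            path,
            np.column_stack([self.times, self.flow_mlps]),
            delimiter=",",
            header="time_s,flow_mlps",
        )

    def flow(self, t) -> np.ndarray:
        """Flow rate [m^3/s] at time(s) ``t`` (periodic)."""
        tt = np.mod(np.asarray(t, dtype=float), self.period)
        tp = np.r_[self.times, self.times[0] + self.period]
        qp = np.r_[self.flow_mlps, self.flow_mlps[0]]
        return np.interp(tt, tp, qp) * 1e-6

    def mean_flow(self) -> float:
        """Period-average flow [m^3/s] (trapezoid over the closed cycle)."""
        tp = np.r_[self.times, self.times[0] + self.period]
        qp = np.r_[self.flow_mlps, self.flow_mlps[0]]
        return float(np.trapezoid(qp, tp) / self.period * 1e-6)


@dataclass
class BoundaryLink:
    """A lattice link cut by the vessel surface.

    ``direction`` points from the fluid node towards the solid side; ``q``
    is the wall fraction along the link; ``u_w`` the prescribed wall
    velocity in lattice units (zero on no-slip walls, normal-directed on
    inlets).
    """

    node: int
    direction: int
    q: float
    tag: str = "wall"
    u_w: np.ndarray = None

    def __post_init__(self):
        if not 0.0 <= self.q < 1.0:
            raise ValueError("q must lie in [0, 1)")
        if self.u_w is None:
            self.u_w = np.zeros(3)
        self.u_w = np.asarray(self.u_w, dtype=float)
        if self.tag == "wall" and np.any(self.u_w != 0):
            raise ValueError("wall links carry zero velocity")


def interpolated_bounce_back(
    link: BoundaryLink,
    f_coll_x: np.ndarray,
    f_coll_up: np.ndarray | None,
    lattice: Lattice | None = None,
    rho0: float = 1.0,
) -> float:
    """Reflected distribution ``f_i'`` at the boundary node.

    Two-point interpolation for ``q < 1/2`` using the post-collision values
    at ``x`` and at the upstream node ``x - c_i``; the one-node form for
    ``q >= 1/2``.  The moving-wall momentum source is
    ``alpha_i (c_i' . u_w)`` with ``alpha_i = 2 w_i rho0 / cs^2``, halved at
    ``q -> 1`` through the ``1/(2q)`` prefactor; at ``q = 1/2`` and
    ``u_w = 0`` both branches reduce to plain bounce-back.

    Parameters
    ----------
    f_coll_x, f_coll_up : (19,) arrays
        Post-collision distributions at the boundary node and at the node
        one cell upstream along the link (``None`` triggers the q=1/2
        fallback for one-node-thick regions).
    """
    if lattice is None:
        lattice = build_d3q19()
    i = link.direction
    j = int(lattice.opposite[i])
    q = link.q
    alpha = 2.0 * lattice.w[i] * rho0 / lattice.cs2
    mw = alpha * float(lattice.c[j] @ link.u_w)
    if q < 0.5:
        if f_coll_up is None:
            return float(f_coll_x[i] + mw)
        return float(
            2.0 * q * f_coll_x[i] + (1.0 - 2.0 * q) * f_coll_up[i] + mw
        )
    return float(
        (0.5 / q) * f_coll_x[i]
        + ((2.0 * q - 1.0) / (2.0 * q)) * f_coll_x[j]
        + mw * (0.5 / q)
    )


def neq_extrapolation_outlet(
    f_neigh: np.ndarray,
    op: MRTOperator,
    p_target_lbm: float = 0.0,
    rho_ref: float = 1.0,
) -> np.ndarray:
    """All 19 distributions at a pressure-outlet node.

    ``f_i(x) = f_i^eq(rho_t, u_nb) + [(I - Omega) (f - f^eq)](x_nb)`` with
    ``rho_t = rho_ref + p_target/cs^2`` (a zero gauge pressure keeps the
    reference lattice density of 1).
    """
    lattice = op.lattice or build_d3q19()
    f_neigh = np.asarray(f_neigh, dtype=float)
    rho_nb = f_neigh.sum()
    u_nb = (f_neigh @ lattice.c.astype(float)) / rho_nb
    feq_nb = equilibrium(rho_nb, u_nb, lattice)
    rho_t = rho_ref + p_target_lbm / lattice.cs2
    feq_t = equilibrium(rho_t, u_nb, lattice)
    A = np.eye(19) - op.omega
    return feq_t + A @ (f_neigh - feq_nb)


def inlet_velocity(
    waveform: Waveform,
    t: float,
    area: float,
    normal: np.ndarray,
    units=None,
):
    """Flat-profile inlet velocity ``u_w = (Q(t)/A) n_hat``.

    Returns the physical velocity vector [m/s]; when a unit system is given
    the lattice-unit vector is returned instead.
    """
    if area <= 0:
        raise ValueError("inlet area must be positive")
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    u = float(waveform.flow(t)) / area * normal
    if units is not None:
        return units.to_lattice_velocity(u)
    return u
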