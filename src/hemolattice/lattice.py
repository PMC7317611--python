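"""D3Q19 lattice definition, MRT collision operator and unit conversion.

The solver evolves particle distribution functions ``f_i`` on a
three-dimensional 19-velocity (D3Q19) lattice.  Collision is performed in
moment space (multiple-relaxation-time, MRT): ``f' = f - M^-1 S (m - m_eq)``
with ``m = M f``.  With a uniform relaxation matrix ``S = (1/tau) I`` the
operator degenerates exactly to the single-relaxation-time BGK update, which
is kept as a test oracle.

All quantities in this module are expressed in lattice units; conversion to
physical units is handled by :class:`UnitSystem`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Lattice",
    "MRTOperator",
    "UnitSystem",
    "build_d3q19",
    "equilibrium",
    "mrt_collide",
    "macroscopics",
    "tau_from_viscosity",
    "viscosity_from_tau",
    "deviatoric_stress",
    "tangential_traction",
    "wall_shear_stress",
]

CS2 = 1.0 / 3.0  # lattice speed of sound squared for isotropic cubic stencils


@dataclass(frozen=True)
class Lattice:
    """Discrete velocity set of the D3Q19 stencil.

    Attributes
    ----------
    c : (19, 3) int array
        Discrete velocities (rest + 6 face + 12 edge directions).
    w : (19,) float array
        Quadrature weights, summing to one.
    opposite : (19,) int array
        Index map with ``c[opposite[i]] == -c[i]``.
    cs2 : float
        Speed of sound squared, 1/3.
    """

    c: np.ndarray
    w: np.ndarray
    opposite: np.ndarray
    cs2: float = CS2

    @property
    def q(self) -> int:
        return len(self.w)


def build_d3q19() -> Lattice:
    """Return the standard D3Q19 lattice (rest, 6 face, 12 edge velocities)."""
    c = [(0, 0, 0)]
    # face-connected
    for a in range(3):
        for s in (1, -1):
            v = [0, 0, 0]
            v[a] = s
            c.append(tuple(v))
    # edge-connected
    for a in range(3):
        for b in range(a + 1, 3):
            for sa in (1, -1):
                for sb in (1, -1):
                    v = [0, 0, 0]
                    v[a] = sa
                    v[b] = sb
                    c.append(tuple(v))
    c = np.array(c, dtype=np.int64)
    w = np.empty(19)
    norms = (c * c).sum(axis=1)
    w[norms == 0] = 1.0 / 3.0
    w[norms == 1] = 1.0 / 18.0
    w[norms == 2] = 1.0 / 36.0
    opposite = np.array(
        [int(np.flatnonzero((c == -ci).all(axis=1))[0]) for ci in c], dtype=np.int64
    )
    return Lattice(c=c, w=w, opposite=opposite)


def equilibrium(rho, u, lattice: Lattice | None = None) -> np.ndarray:
    """Second-order (athermal) equilibrium distributions.

    ``f_i^eq = w_i rho (1 + 3 c_i.u + 9/2 (c_i.u)^2 - 3/2 u.u)``

    Parameters
    ----------
    rho : float or (n,) array
        Lattice density, must be positive.
    u : (3,) or (n, 3) array
        Lattice velocity, ``|u|`` well below 1.

    Returns
    -------
    (19,) or (n, 19) array of equilibrium values whose zeroth and first
    moments equal ``rho`` and ``rho u`` exactly.
    """
    if lattice is None:
        lattice = build_d3q19()
    rho = np.asarray(rho, dtype=float)
    u = np.asarray(u, dtype=float)
    if not (np.all(np.isfinite(rho)) and np.all(np.isfinite(u))):
        raise ValueError("non-finite density or velocity")
    if np.any(rho <= 0):
        raise ValueError("density must be positive")
    scalar = u.ndim == 1
    u2 = np.atleast_2d(u)
    rho2 = np.atleast_1d(rho)
    cu = u2 @ lattice.c.T.astype(float)  # (n, 19)
    usq = (u2 * u2).sum(axis=1)[:, None]
    feq = lattice.w[None, :] * rho2[:, None] * (
        1.0 + 3.0 * cu + 4.5 * cu**2 - 1.5 * usq
    )
    return feq[0] if scalar else feq


def _moment_matrix(lattice: Lattice) -> np.ndarray:
    """Standard (d'Humieres) orthogonal moment basis for D3Q19."""
    c = lattice.c.astype(float)
    cx, cy, cz = c[:, 0], c[:, 1], c[:, 2]
    n2 = cx**2 + cy**2 + cz**2
    rows = [
        np.ones(19),                      # density
        19.0 * n2 - 30.0,                 # energy e
        0.5 * (21.0 * n2**2 - 53.0 * n2 + 24.0),  # energy squared eps
        cx,                               # momentum jx
        (5.0 * n2 - 9.0) * cx,            # energy flux qx
        cy,
        (5.0 * n2 - 9.0) * cy,
        cz,
        (5.0 * n2 - 9.0) * cz,
        3.0 * cx**2 - n2,                 # 3 p_xx
        (3.0 * n2 - 5.0) * (3.0 * cx**2 - n2),
        cy**2 - cz**2,                    # p_ww
        (3.0 * n2 - 5.0) * (cy**2 - cz**2),
        cx * cy,
        cy * cz,
        cx * cz,
        cx * (cy**2 - cz**2),             # m_x
        cy * (cz**2 - cx**2),             # m_y
        cz * (cx**2 - cy**2),             # m_z
    ]
    return np.array(rows)


# moment indices relaxed with the shear rate s_nu
_SHEAR_MOMENTS = (9, 11, 13, 14, 15)


@dataclass(frozen=True)
class MRTOperator:
    """MRT collision operator ``Omega = M^-1 S M`` for D3Q19.

    ``s_nu = 1/tau`` relaxes the five second-order shear moments and fixes
    the kinematic viscosity ``nu_lbm = cs^2 (tau - 1/2)``.  The
    non-hydrodynamic rates default to commonly published values and are
    configurable.
    """

    M: np.ndarray
    Minv: np.ndarray
    S: np.ndarray  # diagonal entries, (19,)
    tau: float
    lattice: Lattice = field(repr=False, default=None)

    @property
    def s_nu(self) -> float:
        return 1.0 / self.tau

    @property
    def omega(self) -> np.ndarray:
        """Collision matrix in distribution space, ``M^-1 S M``."""
        return self.Minv @ (self.S[:, None] * self.M)

    @property
    def nu_lbm(self) -> float:
        return viscosity_from_tau(self.tau)


def make_mrt(
    tau: float,
    lattice: Lattice | None = None,
    s_e: float = 1.19,
    s_eps: float = 1.4,
    s_q: float | None = None,
    s_pi: float = 1.4,
    s_m: float | None = None,
    magic: float = 0.005,
    uniform: bool = False,
) -> MRTOperator:
    """Construct the MRT operator for relaxation time ``tau``.

    The energy-flux rate ``s_q`` defaults to the two-relaxation-time
    pairing ``(1/s_nu - 1/2)(1/s_q - 1/2) = magic``, which keeps the
    effective no-slip wall position essentially independent of viscosity
    as ``tau -> 1/2``; the shipped ``magic`` was calibrated on resolved
    Poiseuille/Womersley pipe benchmarks.  The third-order rate ``s_m``
    keeps the commonly published 1.98 (pairing it too destabilizes curved
    walls near the viscosity floor).  Explicit ``s_q``/``s_m`` override
    the defaults.  With ``uniform=True`` every non-conserved rate is
    ``1/tau``, making the operator mathematically identical to BGK.
    """
    if tau <= 0.5:
        raise ValueError(f"tau must exceed 0.5, got {tau}")
    if lattice is None:
        lattice = build_d3q19()
    M = _moment_matrix(lattice)
    Minv = np.linalg.inv(M)
    s_nu = 1.0 / tau
    if uniform:
        s = np.full(19, s_nu)
    else:
        s_odd = 1.0 / (magic / (tau - 0.5) + 0.5)
        if s_q is None:
            s_q = s_odd
        if s_m is None:
            # under-relaxing the third-order moments as well destabilizes
            # curved walls at tau -> 1/2; they keep the published rate
            s_m = 1.98
        s = np.zeros(19)
        s[1] = s_e
        s[2] = s_eps
        s[4] = s[6] = s[8] = s_q
        s[10] = s[12] = s_pi
        s[16] = s[17] = s[18] = s_m
        for i in _SHEAR_MOMENTS:
            s[i] = s_nu
    # conserved moments (density, momentum) are never relaxed
    s[0] = s[3] = s[5] = s[7] = 0.0
    return MRTOperator(M=M, Minv=Minv, S=s, tau=tau, lattice=lattice)


def mrt_collide(f: np.ndarray, op: MRTOperator) -> np.ndarray:
    """Apply one MRT collision, ``f - M^-1 S (m - m_eq)``.

    ``m_eq = M f^eq`` with ``f^eq`` evaluated at the moments of ``f``, so the
    update conserves density and momentum to round-off and reduces to the
    direct BGK update for uniform ``S``.
    """
    lattice = op.lattice or build_d3q19()
    f = np.asarray(f, dtype=float)
    rho, u, _ = macroscopics(f, lattice)
    feq = equilibrium(rho, u, lattice)
    neq = f - feq
    return f - neq @ op.omega.T


def macroscopics(f: np.ndarray, lattice: Lattice | None = None):
    """Density, velocity and pressure moments of ``f`` (lattice units).

    ``rho = sum_i f_i``, ``u = (1/rho) sum_i c_i f_i``, ``P = rho cs^2``.
    A non-positive density signals a blown-up simulation and raises.
    """
    if lattice is None:
        lattice = build_d3q19()
    f = np.asarray(f, dtype=float)
    if not np.all(np.isfinite(f)):
        raise FloatingPointError("non-finite distribution values")
    rho = f.sum(axis=-1)
    if np.any(rho <= 0):
        raise FloatingPointError(
            "non-positive lattice density: simulation unstable"
        )
    u = (f @ lattice.c.astype(float)) / rho[..., None]
    return rho, u, rho * lattice.cs2


def tau_from_viscosity(nu_lbm: float) -> float:
    """Relaxation time from lattice viscosity, ``tau = nu/cs^2 + 1/2``."""
    if nu_lbm <= 0:
        raise ValueError(f"lattice viscosity must be positive, got {nu_lbm}")
    return nu_lbm / CS2 + 0.5


def viscosity_from_tau(tau: float) -> float:
    return CS2 * (tau - 0.5)


@dataclass(frozen=True)
class UnitSystem:
    """Scale factors between lattice and physical (SI) units.

    ``dx`` [m], ``dt`` [s] and ``dm`` [kg] convert position, time and mass;
    with the customary ``rho_lbm = 1`` the mass scale is ``dm = rho dx^3``.
    """

    dx: float
    dt: float
    dm: float
    rho_lbm: float = 1.0

    def __post_init__(self):
        if min(self.dx, self.dt, self.dm) <= 0:
            raise ValueError("unit scale factors must be positive")

    @classmethod
    def from_density(cls, dx: float, dt: float, rho: float, rho_lbm: float = 1.0):
        return cls(dx=dx, dt=dt, dm=rho * dx**3 / rho_lbm, rho_lbm=rho_lbm)

    # -- conversion helpers (physical = lattice * factor) ------------------
    @property
    def velocity(self) -> float:
        return self.dx / self.dt

    @property
    def pressure(self) -> float:
        return self.dm / (self.dx * self.dt**2)

    @property
    def density(self) -> float:
        return self.dm / self.dx**3

    @property
    def kinematic_viscosity(self) -> float:
        return self.dx**2 / self.dt

    def to_lattice_velocity(self, u_phys):
        return np.asarray(u_phys) / self.velocity

    def to_physical_velocity(self, u_lbm):
        return np.asarray(u_lbm) * self.velocity

    def to_lattice_viscosity(self, nu_phys: float) -> float:
        return nu_phys / self.kinematic_viscosity

    def to_physical_pressure(self, p_lbm):
        return np.asarray(p_lbm) * self.pressure


def deviatoric_stress(f: np.ndarray, op: MRTOperator) -> np.ndarray:
    """Deviatoric (viscous) stress tensor from non-equilibrium distributions.

    Chapman-Enskog gives, at second order,
    ``sigma_ab = -(1 - s_nu/2) (Pi^neq_ab - delta_ab tr(Pi^neq)/3)``
    with ``Pi^neq_ab = sum_i c_ia c_ib (f_i - f_i^eq)``, in lattice units.

    Parameters
    ----------
    f : (..., 19) array
    Returns
    -------
    (..., 3, 3) array of lattice-unit stresses.
    """
    lattice = op.lattice or build_d3q19()
    f = np.asarray(f, dtype=float)
    rho, u, _ = macroscopics(f, lattice)
    neq = f - equilibrium(rho, u, lattice)
    c = lattice.c.astype(float)
    cc = c[:, :, None] * c[:, None, :]  # (19, 3, 3)
    pi = np.einsum("...i,iab->...ab", neq, cc)
    tr = np.trace(pi, axis1=-2, axis2=-1)
    pi = pi - np.eye(3) * (tr[..., None, None] / 3.0)
    return -(1.0 - 0.5 * op.s_nu) * pi


def tangential_traction(
    f: np.ndarray,
    op: MRTOperator,
    units: UnitSystem,
    normal: np.ndarray,
) -> np.ndarray:
    """Tangential viscous traction vector [Pa] at the given nodes."""
    normal = np.asarray(normal, dtype=float)
    sigma = deviatoric_stress(f, op)
    traction = np.einsum("...ab,...b->...a", sigma, normal)
    tn = np.einsum("...a,...a->...", traction, normal)
    return (traction - tn[..., None] * normal) * units.pressure


def wall_shear_stress(
    f: np.ndarray,
    op: MRTOperator,
    units: UnitSystem,
    normal: np.ndarray,
) -> np.ndarray:
    """Wall shear stress magnitude [Pa] at wall-adjacent nodes.

    The tangential component of the viscous traction ``sigma . n`` is
    evaluated from the non-equilibrium moments (no velocity gradients are
    differenced) and converted to physical units with ``dm/(dx dt^2)``.

    Parameters
    ----------
    f : (n, 19) distributions at wall-adjacent fluid nodes
    normal : (n, 3) unit outward surface normals from the nearest triangle
    """
    return np.linalg.norm(
        tangential_traction(f, op, units, normal), axis=-1
    )
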