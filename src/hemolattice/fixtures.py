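"""Synthetic tagged vessel meshes and analytic reference flows.

Everything the rest of the package needs for testing is generated
programmatically here: watertight capped tubes (optionally stenosed or
bulged, the bulge carrying an aneurysm-``dome`` tag), an implicit-surface Y
bifurcation, the Womersley pulsatile-pipe series solution, and a
two-harmonic cardiac-like inlet waveform.

Fixture scale mirrors the cerebral regime: radii 1-3 mm, kinematic
viscosity 4 mm^2/s, density 1000 kg/m^3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import special

from .voxelize import TaggedSurfaceMesh

__all__ = [
    "make_tube",
    "make_stenosed_tube",
    "make_bulged_tube",
    "make_bifurcation",
    "womersley_velocity",
    "womersley_pressure_gradients",
    "AnalyticFlow",
    "poiseuille_pipe",
    "womersley_pipe",
    "plane_channel",
    "default_waveform_samples",
]

NU_BLOOD = 4.0e-6   # m^2/s
RHO_BLOOD = 1000.0  # kg/m^3


def _profile_tube(
    radius_fn: Callable[[np.ndarray], np.ndarray],
    length: float,
    facets: int,
    n_axial: int,
    dome_fn: Callable[[float], bool] | None = None,
) -> TaggedSurfaceMesh:
    """Watertight axisymmetric tube with caps, built ring by ring.

    Inlet cap at z=0, outlet cap at z=length; lateral faces tagged wall (or
    dome where ``dome_fn(z)`` is true).
    """
    if facets < 16:
        raise ValueError("facets must be >= 16")
    if length <= 0:
        raise ValueError("length must be positive")
    z = np.linspace(0.0, length, n_axial + 1)
    r = np.asarray(radius_fn(z), dtype=float)
    if np.any(r <= 0):
        raise ValueError("radius profile must stay positive")
    theta = np.arange(facets) * (2.0 * np.pi / facets)
    verts = []
    for zi, ri in zip(z, r):
        ring = np.stack(
            [ri * np.cos(theta), ri * np.sin(theta), np.full(facets, zi)], axis=1
        )
        verts.append(ring)
    verts = np.concatenate(verts)
    c_in = len(verts)
    verts = np.vstack([verts, [0.0, 0.0, 0.0], [0.0, 0.0, length]])
    c_out = c_in + 1

    faces = []
    tags = []
    for j in range(n_axial):
        zmid = 0.5 * (z[j] + z[j + 1])
        tag = "dome" if (dome_fn is not None and dome_fn(zmid)) else "wall"
        base0 = j * facets
        base1 = (j + 1) * facets
        for k in range(facets):
            k2 = (k + 1) % facets
            # outward orientation (counter-clockwise seen from outside)
            faces.append((base0 + k, base0 + k2, base1 + k))
            faces.append((base0 + k2, base1 + k2, base1 + k))
            tags += [tag, tag]
    for k in range(facets):
        k2 = (k + 1) % facets
        faces.append((c_in, k2, k))            # inlet cap, normal -z
        tags.append("inlet")
        base = n_axial * facets
        faces.append((c_out, base + k, base + k2))  # outlet cap, normal +z
        tags.append("outlet_0")
    mesh = TaggedSurfaceMesh(
        vertices=verts, faces=np.array(faces), face_tags=np.array(tags)
    )
    assert mesh.mesh.is_winding_consistent and mesh.mesh.volume > 0
    return mesh


def make_tube(
    radius: float,
    length: float,
    facets: int = 64,
    extensions: float = 0.0,
    n_axial: int | None = None,
) -> TaggedSurfaceMesh:
    """Straight capped cylinder; caps tagged inlet/outlet, lateral wall.

    ``extensions`` adds straight segments of that length at both ends (the
    total length becomes ``length + 2 * extensions``).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    total = length + 2.0 * extensions
    if n_axial is None:
        n_axial = max(8, int(round(total / (2 * np.pi * radius / facets))))
    return _profile_tube(lambda z: np.full_like(z, radius), total, facets, n_axial)


def make_stenosed_tube(
    radius: float,
    length: float,
    severity: float,
    facets: int = 64,
    stenosis_length: float | None = None,
    n_axial: int | None = None,
) -> TaggedSurfaceMesh:
    """Tube with a smooth cosine constriction at mid-length.

    Minimum diameter is ``(1 - severity) * 2 * radius``.
    """
    if not 0 <= severity < 1:
        raise ValueError("severity must lie in [0, 1)")
    if severity == 0:
        return make_tube(radius, length, facets, n_axial=n_axial)
    w = stenosis_length if stenosis_length is not None else 0.5 * length
    zc = 0.5 * length

    def r(z):
        dz = np.abs(np.asarray(z) - zc)
        bump = np.where(dz < w / 2, 0.5 * (1 + np.cos(2 * np.pi * dz / w)), 0.0)
        return radius * (1.0 - severity * bump)

    if n_axial is None:
        n_axial = max(64, int(round(length / (np.pi * radius / facets))))
    return _profile_tube(r, length, facets, n_axial)


def make_bulged_tube(
    radius: float,
    length: float,
    bulge_radius: float,
    facets: int = 64,
    bulge_length: float | None = None,
    n_axial: int | None = None,
) -> TaggedSurfaceMesh:
    """Tube with a fusiform bulge (aneurysm stand-in) tagged ``dome``."""
    if bulge_radius <= radius:
        raise ValueError("bulge_radius must exceed the tube radius")
    w = bulge_length if bulge_length is not None else 3.0 * radius
    zc = 0.5 * length

    def r(z):
        dz = np.abs(np.asarray(z) - zc)
        bump = np.where(dz < w / 2, 0.5 * (1 + np.cos(2 * np.pi * dz / w)), 0.0)
        return radius + (bulge_radius - radius) * bump

    if n_axial is None:
        n_axial = max(64, int(round(length / (np.pi * radius / facets))))
    thresh = radius + 0.1 * (bulge_radius - radius)

    def is_dome(zmid):
        return float(r(np.array([zmid]))[0]) > thresh

    return _profile_tube(r, length, facets, n_axial, dome_fn=is_dome)


def make_bifurcation(
    r_parent: float,
    r_daughter: float,
    angle: float = np.pi / 5,
    parent_length: float | None = None,
    daughter_length: float | None = None,
    resolution: int = 96,
) -> TaggedSurfaceMesh:
    """Symmetric Y bifurcation from an implicit union of capped cylinders.

    The parent runs along +z from the inlet cap; the daughters leave the
    junction at +-``angle`` from the axis in the x-z plane.  The surface is
    extracted with marching cubes on a grid symmetric about x=0, so the
    mesh is mirror symmetric about the bisecting plane.
    """
    from skimage import measure

    lp = parent_length if parent_length is not None else 6.0 * r_parent
    ld = daughter_length if daughter_length is not None else 6.0 * r_parent
    junction = np.array([0.0, 0.0, lp])
    d1 = np.array([np.sin(angle), 0.0, np.cos(angle)])
    d2 = np.array([-np.sin(angle), 0.0, np.cos(angle)])
    if r_parent <= 0 or r_daughter <= 0:
        raise ValueError("radii must be positive")
    if r_daughter > r_parent * 1.5:
        raise ValueError("daughter radius too large for a clean junction")

    def capped_cyl(p, base, axis, radius, length):
        rel = p - base
        s = rel @ axis
        rad = np.linalg.norm(rel - s[:, None] * axis, axis=1)
        d_side = rad - radius
        d_caps = np.maximum(-s, s - length)
        return np.maximum(d_side, d_caps)

    margin = 2.0 * r_parent
    end1 = junction + ld * d1
    lo = np.minimum.reduce([[-margin, -margin, -margin],
                            end1 - margin, junction - margin])
    hi = np.maximum.reduce([[margin, margin, lp + margin],
                            end1 + margin, junction + margin])
    # symmetric in x about 0
    hx = max(abs(lo[0]), abs(hi[0]))
    lo[0], hi[0] = -hx, hx
    nx = resolution
    xs = np.linspace(lo[0], hi[0], nx)
    ys = np.linspace(lo[1], hi[1], nx)
    zs = np.linspace(lo[2], hi[2], nx)
    P = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1).reshape(-1, 3)
    f_parent = capped_cyl(P, np.zeros(3), np.array([0.0, 0.0, 1.0]), r_parent, lp)
    f_d1 = capped_cyl(P, junction, d1, r_daughter, ld)
    f_d2 = capped_cyl(P, junction, d2, r_daughter, ld)
    sdf = np.minimum(f_parent, np.minimum(f_d1, f_d2)).reshape(nx, nx, nx)
    spacing = (xs[1] - xs[0], ys[1] - ys[0], zs[1] - zs[0])
    verts, faces, _, _ = measure.marching_cubes(sdf, level=0.0, spacing=spacing)
    verts = verts + lo

    import trimesh as _tm

    tm = _tm.Trimesh(vertices=verts, faces=faces, process=True)
    tm.remove_degenerate_faces() if hasattr(tm, "remove_degenerate_faces") else None
    if tm.volume < 0:
        tm.invert()

    # tag faces: caps are planar pieces of the implicit caps
    centroids = tm.triangles_center
    tol = 1.5 * max(spacing)
    tags = np.full(len(tm.faces), "wall", dtype=object)
    # inlet cap: z ~ 0 within parent radius
    near_in = (np.abs(centroids[:, 2]) < tol) & (
        np.linalg.norm(centroids[:, :2], axis=1) < r_parent + tol
    )
    tags[near_in] = "inlet"
    for k, (dvec, name) in enumerate(((d1, "outlet_0"), (d2, "outlet_1"))):
        end = junction + ld * dvec
        rel = centroids - end
        s = rel @ dvec
        rad = np.linalg.norm(rel - s[:, None] * dvec, axis=1)
        near = (np.abs(s) < tol) & (rad < r_daughter + tol)
        tags[near] = name
    return TaggedSurfaceMesh(
        vertices=tm.vertices, faces=tm.faces, face_tags=tags.astype(str)
    )


# ---------------------------------------------------------------------------
# analytic reference flows
# ---------------------------------------------------------------------------

def womersley_velocity(R, nu, rho, pg_harmonics, t, r):
    """Axial velocity of pulsatile pipe flow (Womersley series).

    ``pg_harmonics`` is a list of ``(omega, G)`` with complex amplitude
    ``G`` of the driving pressure gradient ``-dp/dz``; ``omega = 0`` entries
    contribute the steady Poiseuille parabola.  ``t`` and ``r`` broadcast.
    """
    t = np.asarray(t, dtype=float)
    r = np.asarray(r, dtype=float)
    u = np.zeros(np.broadcast(t, r).shape)
    mu = rho * nu
    for omega, G in pg_harmonics:
        if omega == 0:
            u = u + (np.real(G) / (4.0 * mu)) * (R**2 - r**2)
        else:
            lam = 1j**1.5 * np.sqrt(omega / nu)
            j0r = special.jv(0, lam * r)
            j0R = special.jv(0, lam * R)
            term = (G / (1j * rho * omega)) * (1.0 - j0r / j0R) * np.exp(
                1j * omega * t
            )
            u = u + np.real(term)
    return u


def womersley_pressure_gradients(R, nu, rho, flow_harmonics):
    """Convert flow-rate harmonics to pressure-gradient harmonics.

    ``flow_harmonics``: list of ``(omega, Qhat)``, complex ``Qhat`` such that
    ``Q(t) = sum Re[Qhat exp(i omega t)]`` (``omega = 0``: ``Qhat`` real mean).
    Returns matching ``(omega, G)`` pairs for :func:`womersley_velocity`.
    """
    mu = rho * nu
    out = []
    for omega, qhat in flow_harmonics:
        if omega == 0:
            out.append((0.0, 8.0 * mu * np.real(qhat) / (np.pi * R**4)))
        else:
            lam = 1j**1.5 * np.sqrt(omega / nu)
            LR = lam * R
            factor = (np.pi * R**2 / (1j * rho * omega)) * (
                1.0 - 2.0 * special.jv(1, LR) / (LR * special.jv(0, LR))
            )
            out.append((omega, qhat / factor))
    return out


@dataclass
class AnalyticFlow:
    """Closed-form reference flow with velocity/pressure/shear evaluators."""

    name: str
    params: dict
    velocity: Callable = field(repr=False, default=None)       # u(points, t)
    pressure: Callable = field(repr=False, default=None)       # p(points, t)
    wall_shear: Callable = field(repr=False, default=None)     # tau_w(t)

    def residual(self, r_samples, t_samples) -> float:
        """Max residual of the axial momentum equation on a sample grid.

        Checks ``du/dt = -1/rho dp/dz + nu (u'' + u'/r)`` for pipe flows by
        central finite differences (5-point in r, 2-point in t).
        """
        R = self.params["R"]
        nu = self.params["nu"]
        rho = self.params["rho"]
        r = np.asarray(r_samples, dtype=float)
        t = np.asarray(t_samples, dtype=float)
        hr = 1e-4 * R
        ht = 1e-6 * max(self.params.get("period", 1.0), 1e-9)
        res = 0.0
        for ti in t:
            u = lambda rr: self.velocity(rr, ti)
            dudt = (self.velocity(r, ti + ht) - self.velocity(r, ti - ht)) / (2 * ht)
            d2u = (u(r + hr) - 2 * u(r) + u(r - hr)) / hr**2
            du = (u(r + hr) - u(r - hr)) / (2 * hr)
            dpdz = self.pressure_gradient(ti)
            lhs = dudt
            rhs = -dpdz / rho + nu * (d2u + du / np.maximum(r, 1e-12 * R))
            res = max(res, float(np.max(np.abs(lhs - rhs))))
        return res

    def pressure_gradient(self, t):
        gs = self.params["pg_harmonics"]
        return -sum(
            np.real(G * np.exp(1j * omega * t)) if omega else np.real(G)
            for omega, G in gs
        )


def poiseuille_pipe(R, L, Q, nu=NU_BLOOD, rho=RHO_BLOOD) -> AnalyticFlow:
    """Steady Poiseuille pipe flow driven by flow rate ``Q`` [m^3/s]."""
    mu = rho * nu
    G = 8.0 * mu * Q / (np.pi * R**4)  # -dp/dz

    def vel(r, t=0.0):
        return (G / (4 * mu)) * (R**2 - np.asarray(r) ** 2)

    return AnalyticFlow(
        name="poiseuille_pipe",
        params=dict(R=R, L=L, Q=Q, nu=nu, rho=rho, pg_harmonics=[(0.0, G)]),
        velocity=vel,
        pressure=lambda z, t=0.0: -G * np.asarray(z),
        wall_shear=lambda t=0.0: 4.0 * mu * Q / (np.pi * R**3),
    )


def womersley_pipe(R, flow_harmonics, nu=NU_BLOOD, rho=RHO_BLOOD) -> AnalyticFlow:
    """Pulsatile pipe flow from flow-rate harmonics (see conversions above)."""
    pg = womersley_pressure_gradients(R, nu, rho, flow_harmonics)
    omegas = [w for w, _ in flow_harmonics if w > 0]
    period = 2 * np.pi / min(omegas) if omegas else 1.0

    def vel(r, t):
        return womersley_velocity(R, nu, rho, pg, t, r)

    return AnalyticFlow(
        name="womersley_pipe",
        params=dict(
            R=R, nu=nu, rho=rho, pg_harmonics=pg, period=period,
            flow_harmonics=flow_harmonics,
        ),
        velocity=vel,
    )


def plane_channel(h, G, nu=NU_BLOOD, rho=RHO_BLOOD) -> AnalyticFlow:
    """Steady plane channel flow of half-gap ``h`` driven by ``-dp/dx = G``."""
    mu = rho * nu
    return AnalyticFlow(
        name="plane_channel",
        params=dict(R=h, nu=nu, rho=rho, pg_harmonics=[(0.0, G)]),
        velocity=lambda y, t=0.0: (G / (2 * mu)) * (h**2 - np.asarray(y) ** 2),
        wall_shear=lambda t=0.0: G * h,
    )


def make_box(side: float, facets_per_edge: int = 1) -> TaggedSurfaceMesh:
    """Closed axis-aligned cube, every face tagged ``wall`` (sealed domain)."""
    import trimesh as _tm

    tm = _tm.creation.box(extents=[side, side, side])
    if tm.volume < 0:
        tm.invert()
    return TaggedSurfaceMesh(
        vertices=tm.vertices + side / 2,
        faces=tm.faces,
        face_tags=np.array(["wall"] * len(tm.faces)),
    )


def sealed_box_grid(n: int, dx: float):
    """Labeled grid of an n^3 sealed box with walls half-way between nodes.

    All cut links have exactly q = 1/2, where interpolated bounce-back
    degenerates to plain bounce-back and conserves mass to round-off; the
    fixture isolates that property from staircase interpolation effects.
    """
    from .voxelize import (
        LABEL_BULK,
        LABEL_SOLID,
        LABEL_WALL,
        LevelSetGrid,
        TAG_WALL,
    )
    from .lattice import build_d3q19

    pad = 2
    shape = (n + 2 * pad,) * 3
    idx = np.indices(shape).reshape(3, -1).T
    # walls at half-cell outside the node block [pad, pad+n-1]
    lo, hi = pad - 0.5, pad + n - 0.5
    d = np.maximum.reduce(
        [np.maximum(lo - idx[:, k], idx[:, k] - hi) for k in range(3)]
    )
    phi = (d * dx).reshape(shape)
    inside = phi < 0
    labels = np.where(inside, LABEL_BULK, LABEL_SOLID).astype(np.int64)
    lattice = build_d3q19()
    nn = int(np.prod(shape))
    q = np.full((nn, 19), np.nan)
    link_tag = np.full((nn, 19), -1, dtype=np.int64)
    flat_inside = np.flatnonzero(inside.ravel())
    ijk = idx[flat_inside]
    for i in range(1, 19):
        tgt = ijk + lattice.c[i]
        out = ~np.all((tgt >= pad) & (tgt <= pad + n - 1), axis=1)
        rows = flat_inside[out]
        q[rows, i] = 0.5
        link_tag[rows, i] = TAG_WALL
        sub = labels.ravel()
        sub[rows] = LABEL_WALL
    return LevelSetGrid(
        origin=np.zeros(3),
        dx=dx,
        shape=shape,
        phi=phi,
        nearest_tri=np.full(shape, -1, dtype=np.int64),
        labels=labels,
        q=q,
        link_tag=link_tag,
        band=2 * dx,
        mesh=None,
    )


def default_waveform_samples(
    mean_mlps: float = 5.13,
    period: float = 1.0,
    n: int = 64,
    a1: float = 0.5,
    a2: float = 0.2,
):
    """Two-harmonic cardiac-like inlet waveform, sampled.

    ``Q(t) = mean (1 + a1 sin(2 pi t/T) + a2 sin(4 pi t/T + pi/3))`` [ml/s].
    Returns (t, q) arrays covering exactly one period.
    """
    t = np.linspace(0.0, period, n, endpoint=False)
    q = mean_mlps * (
        1.0
        + a1 * np.sin(2 * np.pi * t / period)
        + a2 * np.sin(4 * np.pi * t / period + np.pi / 3)
    )
    return t, q
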