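"""Clinical summary quantities from a completed run.

* pressure-loss coefficient PLc across the aneurysm,
* dome-averaged wall shear stress (AvWSS),
* centerline pressure/velocity profiles per outlet branch, and
* the relative-difference metric used for solver-to-solver comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PlaneProbe",
    "CenterlineProfile",
    "plane_probe",
    "pressure_loss_coefficient",
    "dome_average_wss",
    "relative_difference",
    "centerline_profiles",
    "plc_probes",
    "summarize",
]


@dataclass
class PlaneProbe:
    """Disk probe perpendicular to the centerline.

    ``p_mean`` [Pa] and ``u_mean`` [m/s]: inverse-distance means over fluid
    nodes within one grid spacing of the disk.  ``u_mean`` is the magnitude
    of the area-averaged velocity vector by default.
    """

    center: np.ndarray
    normal: np.ndarray
    radius: float
    p_mean: float = 0.0
    u_mean: float = 0.0
    n_samples: int = 0


@dataclass
class CenterlineProfile:
    """Pressure/velocity sampled along one inlet-to-outlet centerline."""

    branch: int
    arclength: np.ndarray   # (n,) m, monotone
    pressure: np.ndarray    # (n,) Pa
    velocity: np.ndarray    # (n,) m/s (magnitude)


def plane_probe(
    positions: np.ndarray,
    p: np.ndarray,
    u: np.ndarray,
    center,
    normal,
    radius: float,
    thickness: float,
    mean_velocity: str = "vector",
) -> PlaneProbe:
    """Sample mean pressure and velocity on a disk of given radius.

    Nodes within ``thickness`` of the plane and ``radius`` of the axis are
    inverse-distance weighted by their off-plane distance.
    ``mean_velocity='vector'`` reports the magnitude of the averaged
    vector; ``'magnitude'`` averages the magnitudes instead.
    """
    center = np.asarray(center, dtype=float)
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    rel = positions - center
    d_plane = rel @ normal
    d_rad = np.linalg.norm(rel - d_plane[:, None] * normal, axis=1)
    m = (np.abs(d_plane) <= thickness) & (d_rad <= radius)
    n = int(m.sum())
    if n < 10:
        raise ValueError(
            f"plane probe sampled only {n} fluid nodes (need >= 10); "
            "enlarge the disk or refine the grid"
        )
    wgt = 1.0 / (np.abs(d_plane[m]) + 0.1 * thickness)
    wgt /= wgt.sum()
    p_mean = float(wgt @ p[m])
    if mean_velocity == "vector":
        u_mean = float(np.linalg.norm(wgt @ u[m]))
    elif mean_velocity == "magnitude":
        u_mean = float(wgt @ np.linalg.norm(u[m], axis=1))
    else:
        raise ValueError("mean_velocity must be 'vector' or 'magnitude'")
    return PlaneProbe(
        center=center, normal=normal, radius=radius,
        p_mean=p_mean, u_mean=u_mean, n_samples=n,
    )


def pressure_loss_coefficient(inlet: PlaneProbe, outlet: PlaneProbe,
                              rho: float) -> float:
    """PLc = [(p + rho u^2/2)_in - (p + rho u^2/2)_out] / (rho u_in^2/2).

    Total-pressure drop across the aneurysm normalized by the inlet
    dynamic pressure; invariant under a constant pressure offset.
    """
    dyn_in = 0.5 * rho * inlet.u_mean**2
    if dyn_in <= 0:
        raise ValueError("inlet velocity is zero; PLc is undefined")
    total_in = inlet.p_mean + dyn_in
    total_out = outlet.p_mean + 0.5 * rho * outlet.u_mean**2
    return (total_in - total_out) / dyn_in


def dome_average_wss(
    wss: np.ndarray,
    wall_tids: np.ndarray,
    face_tags: np.ndarray,
    face_areas: np.ndarray,
    dome_tag: str = "dome",
) -> float:
    """Area-weighted mean WSS over wall nodes mapped to dome triangles.

    Each wall-adjacent node carries the tag of its nearest triangle; the
    weights are the areas of those triangles (so the average approximates
    the surface integral over the tagged patch).
    """
    if not np.any(face_tags == dome_tag):
        raise ValueError(f"mesh has no {dome_tag!r} faces")
    on_dome = face_tags[wall_tids] == dome_tag
    if not np.any(on_dome):
        raise ValueError("no wall nodes map to the dome patch")
    w = face_areas[wall_tids[on_dome]]
    return float((wss[on_dome] * w).sum() / w.sum())


def relative_difference(
    profile_a: CenterlineProfile | np.ndarray,
    profile_b: CenterlineProfile | np.ndarray,
    values: str = "pressure",
) -> np.ndarray:
    """Pointwise relative difference d(x) [%] against a reference profile.

    ``d(x) = |f_a(x) - f_b(x)| / mean(f_b) * 100`` with the mean of the
    reference profile taken over the whole centerline.
    """
    if isinstance(profile_a, CenterlineProfile):
        fa = getattr(profile_a, values)
        fb = getattr(profile_b, values)
        if not np.allclose(profile_a.arclength, profile_b.arclength):
            raise ValueError("profiles must share arc-length positions")
    else:
        fa = np.asarray(profile_a, dtype=float)
        fb = np.asarray(profile_b, dtype=float)
    ref = float(np.mean(fb))
    if ref == 0:
        raise ValueError("reference profile has zero mean")
    return np.abs(fa - fb) / ref * 100.0


def centerline_profiles(
    result,
    which: str = "avg",
    n_points: int = 700,
) -> list:
    """Sample p and |u| along each inlet-to-outlet centerline.

    Values are inverse-distance interpolated from fluid nodes within 1.5
    grid spacings of each centerline point.
    """
    state = result.state
    net = result.network
    fields = result.fields[which]
    positions = state.positions()
    profiles = []
    for branch, chain in enumerate(_root_to_leaf_chains(net)):
        pts, arcs = chain
        s = np.linspace(0.0, arcs[-1], n_points)
        samples = np.column_stack(
            [np.interp(s, arcs, pts[:, k]) for k in range(3)]
        )
        p_s = np.empty(n_points)
        u_s = np.empty(n_points)
        for i, q in enumerate(samples):
            d = np.linalg.norm(positions - q, axis=1)
            m = d < 1.5 * state.units.dx
            if not np.any(m):
                k = int(np.argmin(d))
                m = d <= d[k] + 0.5 * state.units.dx
            wgt = 1.0 / (d[m] + 0.1 * state.units.dx)
            wgt /= wgt.sum()
            p_s[i] = wgt @ fields["p"][m]
            u_s[i] = np.linalg.norm(wgt @ fields["u"][m])
        profiles.append(
            CenterlineProfile(
                branch=branch, arclength=s, pressure=p_s, velocity=u_s
            )
        )
    return profiles


def _root_to_leaf_chains(net):
    """Concatenated centerline polylines from the inlet to each leaf."""
    children = net.children
    chains = []

    def walk(seg_id, pts_so_far):
        seg = net.segments[seg_id]
        pts = seg.points if not pts_so_far else np.vstack(
            [pts_so_far, seg.points]
        )
        kids = children.get(seg_id, [])
        if not kids:
            d = np.linalg.norm(np.diff(pts, axis=0), axis=1)
            chains.append((pts, np.r_[0.0, np.cumsum(d)]))
        else:
            for k in kids:
                walk(k, pts)

    walk(0, None)
    return chains


def plc_probes(
    result,
    which: str = "avg",
    offset: float = 1.0e-3,
    mean_velocity: str = "vector",
):
    """Inlet/outlet PLc probes 1 mm up/downstream of the dome extent.

    The dome extent is the arc-length range of wall nodes whose nearest
    triangle is dome-tagged, projected on the main centerline.
    """
    state = result.state
    mesh = result.mesh
    net = result.network
    fields = result.fields[which]
    dome_faces = np.flatnonzero(mesh.face_tags == "dome")
    if len(dome_faces) == 0:
        raise ValueError("mesh has no dome patch")
    tri = mesh.vertices[mesh.faces[dome_faces]]
    dome_pts = tri.mean(axis=1)

    pts, arcs = _root_to_leaf_chains(net)[0]
    # project dome triangles on the centerline
    proj = []
    for q in dome_pts:
        proj.append(arcs[np.argmin(np.linalg.norm(pts - q, axis=1))])
    s0, s1 = min(proj) - offset, max(proj) + offset
    s0 = max(s0, arcs[1])
    s1 = min(s1, arcs[-2])
    positions = state.positions()
    probes = []
    for s in (s0, s1):
        center = np.array([np.interp(s, arcs, pts[:, k]) for k in range(3)])
        i = np.searchsorted(arcs, s)
        tang = pts[min(i + 1, len(pts) - 1)] - pts[max(i - 1, 0)]
        tang = tang / np.linalg.norm(tang)
        radius = _local_radius(net, center)
        probes.append(
            plane_probe(
                positions, fields["p"], fields["u"], center, tang,
                radius=radius, thickness=state.units.dx,
                mean_velocity=mean_velocity,
            )
        )
    return probes[0], probes[1]


def _local_radius(net, point):
    best = None
    for seg in net.segments:
        d = np.linalg.norm(seg.points - point, axis=1)
        i = int(np.argmin(d))
        if best is None or d[i] < best[0]:
            best = (d[i], seg.r0[i])
    return float(1.5 * best[1])


def summarize(result, rho: float | None = None) -> dict:
    """One-row summary: PLc (avg and peak) and AvWSS if a dome exists."""
    rho = rho if rho is not None else result.config.rho
    out = {}
    mesh = result.mesh
    state = result.state
    if np.any(mesh.face_tags == "dome"):
        for which in ("avg", "peak"):
            pin, pout = plc_probes(result, which=which)
            out[f"plc_{which}"] = pressure_loss_coefficient(pin, pout, rho)
        tri = mesh.vertices[mesh.faces]
        areas = 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
        )
        wall_flat = state.node_flat[state.wall_nodes]
        tids = state.grid.nearest_tri.ravel()[wall_flat]
        for which in ("avg", "peak"):
            out[f"avwss_{which}"] = dome_average_wss(
                result.fields[which]["wss"], tids, mesh.face_tags, areas
            )
    return out
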