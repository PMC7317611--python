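"""Cross-sectionally averaged 1D blood-flow model on centerlines.

The reduced-order model (ROM) solves mass and momentum conservation for
flow rate ``q(x, t)`` and pressure ``p(x, t)`` on the vessel's centerline
network,

    dA/dt + dq/dx = 0
    dq/dt + d(alpha q^2/A)/dx + (A/rho) dp/dx = K_R q/A

closed by the tube law ``p = p0 + (4 E h / 3 r0)(1 - sqrt(A0/A))``.  A
parabolic cross-sectional profile fixes ``alpha = 4/3`` and
``K_R = -8 pi nu``.  The wall stiffness is set so the pulse-wave speed far
exceeds physiological speeds (numerically rigid): the ROM's only job is a
robust early estimate of the peak velocity ``u_max ~ max 2 q / A`` that
seeds the resolution autotuner, so bifurcations impose continuity of flow
and of total pressure ``p + rho (q/A)^2 / 2`` via linearized
characteristics, accurate in the rigid regime.

Centerlines are extracted geometrically: a provisional coarse voxelization
gives an interior distance map, shortest paths from the inlet to each
outlet that favour the mid-vessel ridge give the polylines, and the local
radius/area come from exact point-to-surface distances and plane-mesh
cross sections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import ndimage, sparse
from scipy.sparse import csgraph

from . import _geom
from .boundaries import Waveform
from .voxelize import GeometryError, TaggedSurfaceMesh, voxelize

__all__ = [
    "Segment1D",
    "VesselNetwork1D",
    "Solution1D",
    "extract_network",
    "load_centerlines",
    "solve_1d",
    "estimate_umax",
]

ALPHA_PARABOLIC = 4.0 / 3.0
WAVE_SPEED_RIGID = 120.0  # m/s, well above physiological pulse-wave speeds


@dataclass
class Segment1D:
    """One centerline branch: ordered points with reference radius/area."""

    points: np.ndarray      # (n, 3) m
    r0: np.ndarray          # (n,) m
    A0: np.ndarray          # (n,) m^2
    parent: int = -1        # parent segment id (-1 for the inlet trunk)
    outlet: int = -1        # outlet id if this is a leaf

    @property
    def arclength(self) -> np.ndarray:
        d = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.r_[0.0, np.cumsum(d)]


@dataclass
class VesselNetwork1D:
    """Centerline tree rooted at the inlet.

    ``E`` and ``h`` parameterize the tube-law stiffness
    ``G = 4 E h / (3 r0)``; the default targets a rigid-regime wave speed
    of ~120 m/s at the mean radius.
    """

    segments: list
    E: float = None         # Pa
    h: float = None         # m
    p0: float = 0.0         # Pa
    rho: float = 1000.0

    def __post_init__(self):
        if self.E is None or self.h is None:
            # G = 2 rho c0^2 at the mean radius
            rmean = float(np.mean([s.r0.mean() for s in self.segments]))
            G = 2.0 * self.rho * WAVE_SPEED_RIGID**2
            if self.h is None:
                self.h = 0.1 * rmean
            if self.E is None:
                self.E = 3.0 * G * rmean / (4.0 * self.h)
        for s in self.segments:
            if np.any(s.A0 <= 0):
                raise ValueError("reference areas must be positive")

    def stiffness(self, r0) -> np.ndarray:
        """Tube-law coefficient ``G(x) = 4 E h / (3 r0)`` [Pa]."""
        return 4.0 * self.E * self.h / (3.0 * np.asarray(r0))

    @property
    def children(self) -> dict:
        out = {}
        for i, s in enumerate(self.segments):
            if s.parent >= 0:
                out.setdefault(s.parent, []).append(i)
        return out

    def min_diameter(self) -> float:
        return 2.0 * float(min(s.r0.min() for s in self.segments))


@dataclass
class Solution1D:
    """Flow, pressure and area on the (cells x stored-times) grid."""

    network: VesselNetwork1D
    times: np.ndarray          # (nt,)
    q: np.ndarray              # (nt, ncell) m^3/s
    p: np.ndarray              # (nt, ncell) Pa
    A: np.ndarray              # (nt, ncell) m^2
    seg_slices: list           # cell slice per segment
    cell_x: np.ndarray         # (ncell,) arc length within the segment


def estimate_umax(sol: Solution1D) -> float:
    """Peak physical velocity ``max_x,t 2 q / A`` (parabolic profile)."""
    return float(np.max(np.abs(2.0 * sol.q / sol.A)))


# ---------------------------------------------------------------------------
# centerline extraction
# ---------------------------------------------------------------------------

def extract_network(
    mesh: TaggedSurfaceMesh,
    dx: float | None = None,
    smooth_window: int = 5,
) -> VesselNetwork1D:
    """Centerline network from the tagged surface mesh.

    A coarse provisional voxelization provides an interior distance map;
    minimum-cost paths from the inlet to each outlet that follow the
    maximal-distance ridge give the branch polylines, refined to the local
    distance maximum and equipped with exact point-to-surface radii and
    plane-intersection areas.
    """
    mesh.require_watertight()
    a_in = mesh.patch_area("inlet")
    d_inlet = 2.0 * np.sqrt(a_in / np.pi)
    if dx is None:
        dx = d_inlet / 8.0
        extent = mesh.vertices.max(axis=0) - mesh.vertices.min(axis=0)
        while np.prod(np.ceil(extent / dx) + 7) > 1.5e6:
            dx *= 1.26
    grid = voxelize(mesh, dx)
    inside = grid.phi <= 0
    edt = ndimage.distance_transform_edt(inside) * dx

    n_out = mesh.n_outlets
    if n_out < 1:
        raise GeometryError("mesh has no outlet tags")

    seeds = {}
    for tag in ["inlet"] + [f"outlet_{k}" for k in range(n_out)]:
        cen = mesh.patch_centroid(tag)
        inward = -mesh.patch_normal(tag)
        p = cen + inward * 1.5 * dx
        ijk = np.round((p - grid.origin) / dx).astype(int)
        ijk = np.clip(ijk, 0, np.array(grid.shape) - 1)
        if not inside[tuple(ijk)]:
            # search a small neighbourhood for an interior node
            cand = np.argwhere(inside)
            d = np.linalg.norm(cand - ijk, axis=1)
            ijk = cand[np.argmin(d)]
        seeds[tag] = tuple(ijk)

    paths = _ridge_paths(inside, edt, dx, seeds, n_out)
    raw_segments = _merge_paths(paths)

    # polish each polyline and attach radii/areas; the local radius is the
    # distance to the *wall* surface (caps would otherwise clip the ends)
    wall_faces = mesh.faces[
        (mesh.face_tags == "wall") | (mesh.face_tags == "dome")
    ]
    tri_verts = np.ascontiguousarray(mesh.vertices[wall_faces], dtype=np.float64)
    cell = max(np.sqrt(np.median(
        np.linalg.norm(np.cross(tri_verts[:, 1] - tri_verts[:, 0],
                                tri_verts[:, 2] - tri_verts[:, 0]), axis=1))), dx)
    buckets = _geom.TriangleBuckets(tri_verts, cell=cell)
    segments = []
    for parent, outlet, chain in raw_segments:
        pts = grid.origin + np.asarray(chain, dtype=float) * dx
        # iterated smoothing removes the voxel-path zig-zag (which would
        # otherwise inflate arc lengths by tens of percent)
        pts = _resample_polyline(pts, dx)
        for _ in range(3):
            pts = _smooth_polyline(pts, smooth_window)
            pts = _resample_polyline(pts, dx)
        pts = _recenter(pts, grid, edt, dx)
        pts = _polish_inscribed(pts, buckets, dx)
        r0, _ = _geom.closest_triangles(
            np.ascontiguousarray(pts), buckets.tri_verts, buckets.origin,
            buckets.cell, buckets.shape, buckets.starts, buckets.items,
        )
        A0 = _section_areas(mesh, pts, r0)
        segments.append(
            Segment1D(points=pts, r0=r0, A0=A0, parent=parent, outlet=outlet)
        )
    return VesselNetwork1D(segments=segments)


def load_centerlines(path) -> VesselNetwork1D:
    """User-supplied centerlines instead of geometric extraction.

    CSV columns: ``segment, parent, outlet, x, y, z, r`` — one row per
    centerline point, points of a segment in order, ``parent = -1`` for
    the inlet trunk, ``outlet`` the outlet id for leaves (else -1).
    Reference areas are ``pi r^2``.
    """
    rows = np.genfromtxt(path, delimiter=",", names=True)
    segments = []
    for sid in np.unique(rows["segment"]).astype(int):
        sel = rows["segment"].astype(int) == sid
        pts = np.column_stack([rows["x"][sel], rows["y"][sel], rows["z"][sel]])
        r0 = np.asarray(rows["r"][sel], dtype=float)
        segments.append(
            Segment1D(
                points=pts,
                r0=r0,
                A0=np.pi * r0**2,
                parent=int(rows["parent"][sel][0]),
                outlet=int(rows["outlet"][sel][0]),
            )
        )
    return VesselNetwork1D(segments=segments)


def _ridge_paths(inside, edt, dx, seeds, n_out):
    """Minimum-cost voxel paths inlet -> each outlet along the ridge."""
    shape = inside.shape
    flat_ids = np.flatnonzero(inside.ravel())
    remap = -np.ones(inside.size, dtype=np.int64)
    remap[flat_ids] = np.arange(len(flat_ids))
    ijk = np.stack(np.unravel_index(flat_ids, shape), axis=1)
    rows, cols, weights = [], [], []
    w_node = dx / (edt.ravel()[flat_ids] + 0.5 * dx) ** 2
    # small length penalty: keeps paths on the ridge but stops them from
    # wandering through wide regions where the ridge weight is nearly flat
    w_node = w_node + 0.5 * w_node.min()
    for off in _offsets26():
        tgt = ijk + off
        ok = np.all((tgt >= 0) & (tgt < np.array(shape)), axis=1)
        tflat = (tgt[:, 0] * shape[1] + tgt[:, 1]) * shape[2] + tgt[:, 2]
        tid = remap[np.where(ok, tflat, 0)]
        ok &= tid >= 0
        step = np.linalg.norm(off)
        rows.append(np.flatnonzero(remap[flat_ids] >= 0)[ok])
        cols.append(tid[ok])
        weights.append(step * 0.5 * (w_node[ok] + w_node[tid[ok]]))
    g = sparse.csr_matrix(
        (np.concatenate(weights), (np.concatenate(rows), np.concatenate(cols))),
        shape=(len(flat_ids), len(flat_ids)),
    )
    src = remap[np.ravel_multi_index(seeds["inlet"], shape)]
    _, pred = csgraph.dijkstra(
        g, indices=src, return_predecessors=True, directed=False
    )
    paths = []
    for k in range(n_out):
        tgt = remap[np.ravel_multi_index(seeds[f"outlet_{k}"], shape)]
        chain = []
        node = tgt
        guard = 0
        while node != src and node >= 0:
            chain.append(node)
            node = pred[node]
            guard += 1
            if guard > len(flat_ids):
                raise GeometryError("centerline path search failed")
        if node < 0:
            raise GeometryError(
                f"outlet {k} is not connected to the inlet in the voxel grid"
            )
        chain.append(src)
        chain.reverse()
        paths.append(ijk[np.array(chain)])
    return paths


def _offsets26():
    out = []
    for a in (-1, 0, 1):
        for b in (-1, 0, 1):
            for c in (-1, 0, 1):
                if (a, b, c) != (0, 0, 0):
                    out.append(np.array([a, b, c]))
    return out


def _merge_paths(paths):
    """Split voxel paths sharing a common prefix into a segment tree.

    Returns a list of (parent_id, outlet_id, chain) in parent-first order.
    """
    items = [(tuple(map(tuple, p)), k) for k, p in enumerate(paths)]
    segments = []

    def recurse(group, parent, start):
        # longest common prefix of all paths in the group from ``start``
        first = group[0][0]
        n = len(first)
        for path, _ in group[1:]:
            n = min(n, len(path))
        end = start
        while end < n and all(p[end] == first[end] for p, _ in group):
            end += 1
        chain = [first[i] for i in range(max(start - 1, 0), end)]
        if len(group) == 1:
            chain = [first[i] for i in range(max(start - 1, 0), len(first))]
            segments.append((parent, group[0][1], chain))
            return
        seg_id = len(segments)
        segments.append((parent, -1, chain))
        buckets = {}
        for path, k in group:
            key = path[end] if end < len(path) else None
            buckets.setdefault(key, []).append((path, k))
        for sub in buckets.values():
            recurse(sub, seg_id, end)

    recurse(items, -1, 0)
    return segments


def _resample_polyline(pts, ds):
    d = np.r_[0.0, np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))]
    if d[-1] < 2 * ds:
        return pts
    s = np.linspace(0.0, d[-1], max(int(d[-1] / ds) + 1, 4))
    return np.column_stack([np.interp(s, d, pts[:, k]) for k in range(3)])


def _smooth_polyline(pts, window):
    """Moving average over full windows only; endpoints stay fixed."""
    if window <= 1 or len(pts) < window + 2:
        return pts
    half = window // 2
    out = pts.copy()
    csum = np.cumsum(np.vstack([np.zeros(3), pts]), axis=0)
    for k in range(half, len(pts) - half):
        out[k] = (csum[k + half + 1] - csum[k - half]) / (2 * half + 1)
    return out


def _recenter(pts, grid, edt, dx, iters=3):
    """Push points to the local maximum of the interior distance map."""
    out = pts.copy()
    tangents = np.gradient(out, axis=0)
    tangents /= np.maximum(np.linalg.norm(tangents, axis=1), 1e-30)[:, None]
    for _ in range(iters):
        g = _trilinear_gradient(edt, grid.origin, dx, out)
        g -= (np.einsum("ij,ij->i", g, tangents))[:, None] * tangents
        out = out + 0.5 * dx * np.sign(g) * np.minimum(np.abs(g), 1.0)
        vals = _trilinear(edt, grid.origin, dx, out)
        bad = vals <= 0
        if bad.any():
            out[bad] = pts[bad]
    out[0] = pts[0]
    out[-1] = pts[-1]
    return out


def _polish_inscribed(pts, buckets, dx, iters=7):
    """Sub-voxel centering: maximize the exact wall distance in the plane
    perpendicular to the local tangent (pattern search)."""
    out = pts.copy()
    tangents = np.gradient(out, axis=0)
    tangents /= np.maximum(np.linalg.norm(tangents, axis=1), 1e-30)[:, None]

    def dist(p):
        d, _ = _geom.closest_triangles(
            np.ascontiguousarray(p.reshape(1, 3)), buckets.tri_verts,
            buckets.origin, buckets.cell, buckets.shape, buckets.starts,
            buckets.items,
        )
        return d[0]

    for k in range(len(out)):
        t = tangents[k]
        a = np.array([1.0, 0.0, 0.0])
        if abs(t @ a) > 0.9:
            a = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(t, a)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(t, e1)
        p = out[k]
        best = dist(p)
        h = 0.7 * dx
        for _ in range(iters):
            moved = False
            for step in (h * e1, -h * e1, h * e2, -h * e2):
                d = dist(p + step)
                if d > best:
                    best = d
                    p = p + step
                    moved = True
            if not moved:
                h *= 0.5
        out[k] = p
    return out


def _trilinear(field, origin, dx, pts):
    rel = (pts - origin) / dx
    idx = np.clip(np.floor(rel).astype(int), 0,
                  np.array(field.shape) - 2)
    frac = np.clip(rel - idx, 0.0, 1.0)
    out = np.zeros(len(pts))
    for di in (0, 1):
        for dj in (0, 1):
            for dk in (0, 1):
                w = (
                    (frac[:, 0] if di else 1 - frac[:, 0])
                    * (frac[:, 1] if dj else 1 - frac[:, 1])
                    * (frac[:, 2] if dk else 1 - frac[:, 2])
                )
                out += w * field[idx[:, 0] + di, idx[:, 1] + dj, idx[:, 2] + dk]
    return out


def _trilinear_gradient(field, origin, dx, pts):
    g = np.empty((len(pts), 3))
    for a in range(3):
        e = np.zeros(3)
        e[a] = 0.5 * dx
        g[:, a] = (
            _trilinear(field, origin, dx, pts + e)
            - _trilinear(field, origin, dx, pts - e)
        ) / dx
    return g


def _section_areas(mesh: TaggedSurfaceMesh, pts, r0):
    """Cross-sectional areas from plane-mesh intersections.

    Falls back to ``pi r0^2`` where the local section loop cannot be
    isolated (e.g. oblique cuts near junctions).
    """
    import trimesh.intersections as tin

    tangents = np.gradient(pts, axis=0)
    tangents /= np.maximum(np.linalg.norm(tangents, axis=1), 1e-30)[:, None]
    areas = np.pi * np.asarray(r0) ** 2
    tm = mesh.mesh
    for i, (p, t) in enumerate(zip(pts, tangents)):
        try:
            lines = tin.mesh_plane(tm, plane_normal=t, plane_origin=p)
        except Exception:
            continue
        if len(lines) == 0:
            continue
        area = _loop_area(lines, p, t, max_r=4.0 * max(r0[i], 1e-9))
        if area is not None:
            areas[i] = area
    return areas


def _loop_area(lines, center, normal, max_r):
    """Area of the closed intersection loop surrounding ``center``."""
    # basis in the cutting plane
    a = np.array([1.0, 0.0, 0.0])
    if abs(normal @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(normal, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    rel = lines - center
    uv = np.stack([rel @ e1, rel @ e2], axis=-1)  # (nseg, 2, 2)
    keep = np.linalg.norm(uv, axis=-1).max(axis=1) < max_r
    uv = uv[keep]
    if len(uv) < 3:
        return None
    # chain segments into a loop by endpoint matching
    scale = np.abs(uv).max()
    key = lambda p: (round(p[0] / scale, 9), round(p[1] / scale, 9))
    links = {}
    for s, seg in enumerate(uv):
        for end in range(2):
            links.setdefault(key(seg[end]), []).append((s, end))
    used = np.zeros(len(uv), dtype=bool)
    # start from the segment closest to the center
    start = int(np.argmin(np.linalg.norm(uv.mean(axis=1), axis=1)))
    loop = [uv[start][0], uv[start][1]]
    used[start] = True
    for _ in range(len(uv)):
        k = key(loop[-1])
        nxt = [(s, e) for s, e in links.get(k, []) if not used[s]]
        if not nxt:
            break
        s, e = nxt[0]
        used[s] = True
        loop.append(uv[s][1 - e])
        if key(loop[-1]) == key(loop[0]):
            break
    loop = np.asarray(loop)
    if len(loop) < 4 or key(loop[-1]) != key(loop[0]):
        return None
    x, y = loop[:-1, 0], loop[:-1, 1]
    xn, yn = loop[1:, 0], loop[1:, 1]
    return abs(0.5 * np.sum(x * yn - xn * y))


# ---------------------------------------------------------------------------
# 1D solver (MacCormack with linearized-characteristic couplings)
# ---------------------------------------------------------------------------

def solve_1d(
    net: VesselNetwork1D,
    waveform: Waveform,
    nu: float = 4.0e-6,
    rho: float | None = None,
    cycles: int = 2,
    n_cells: int = 50,
    cfl: float = 0.8,
    store_points: int = 200,
    ramp_frac: float = 0.1,
) -> Solution1D:
    """March the 1D network through ``cycles`` periods of the waveform.

    Interior cells use MacCormack; the inlet imposes ``q = Q(t)``, leaves
    impose ``p = 0``, and bifurcations impose flow and total-pressure
    continuity through linearized characteristics.  The time step obeys an
    internal CFL bound on the (stiff) wave speed; the last cycle is stored
    at ``store_points`` instants.  The inflow ramps up over the first
    ``ramp_frac`` of a period, suppressing the start-up water-hammer wave
    the rigid network would otherwise sustain for many transit times.
    """
    if rho is None:
        rho = net.rho
    segs = net.segments
    nseg = len(segs)
    seg_slices = []
    A0_list, r0_list, ds_list = [], [], []
    ncell = 0
    for s in segs:
        arc = s.arclength
        length = arc[-1]
        n = max(8, min(n_cells, int(length / max(arc[1], 1e-9)) + 1))
        x = np.linspace(0, length, n)
        A0 = np.interp(x, arc, s.A0)
        r0 = np.interp(x, arc, s.r0)
        seg_slices.append(slice(ncell, ncell + n))
        ncell += n
        A0_list.append(A0)
        r0_list.append(r0)
        ds_list.append(x[1] - x[0])
    A0 = np.concatenate(A0_list)
    r0 = np.concatenate(r0_list)
    ds = np.array(ds_list)
    G = net.stiffness(r0)
    c0 = np.sqrt(G / (2.0 * rho))

    seg_start = np.array([sl.start for sl in seg_slices], dtype=np.int64)
    seg_end = np.array([sl.stop for sl in seg_slices], dtype=np.int64)

    children = net.children
    junctions = []
    for parent, kids in sorted(children.items()):
        if len(kids) > 2:
            raise GeometryError("junctions with more than two children "
                                "are not supported")
        if len(kids) == 1:
            kids = [kids[0], kids[0]]  # degenerate; treated as pass-through
        junctions.append((parent, kids[0], kids[1], len(children[parent])))
    junc = np.array(
        [[p, k1, k2, nk] for p, k1, k2, nk in junctions], dtype=np.int64
    ).reshape(-1, 4)
    leaves = np.array(
        [i for i, s in enumerate(segs) if i not in children], dtype=np.int64
    )

    T = waveform.period
    dt = cfl * float(np.min(ds / (c0.max() + 10.0)))
    nsteps_cycle = int(np.ceil(T / dt))
    dt = T / nsteps_cycle
    total = nsteps_cycle * cycles

    tw = np.r_[waveform.times, waveform.times[0] + T]
    qw = np.r_[waveform.flow_mlps, waveform.flow_mlps[0]] * 1e-6

    store_every = max(1, nsteps_cycle // store_points)
    n_store = nsteps_cycle // store_every
    qs = np.zeros((n_store, ncell))
    As = np.zeros((n_store, ncell))
    ts = np.zeros(n_store)

    A = A0.copy()
    q = np.zeros(ncell)
    _march(
        A, q, A0, G, c0, rho, nu, ds, dt, total, nsteps_cycle, store_every,
        seg_start, seg_end, junc, leaves, tw, qw, T, qs, As, ts,
        ramp_frac * T,
    )
    p = G[None, :] * (1.0 - np.sqrt(A0[None, :] / As)) + net.p0
    cell_x = np.concatenate(
        [np.linspace(0, (seg_end[i] - seg_start[i] - 1) * ds[i],
                     seg_end[i] - seg_start[i]) for i in range(nseg)]
    )
    return Solution1D(
        network=net, times=ts, q=qs, p=p, A=As,
        seg_slices=seg_slices, cell_x=cell_x,
    )


@njit(cache=True)
def _tube_pressure(A, A0, G):
    return G * (1.0 - np.sqrt(A0 / A))


@njit(cache=True)
def _march(
    A, q, A0, G, c0, rho, nu, ds, dt, total, nsteps_cycle, store_every,
    seg_start, seg_end, junc, leaves, tw, qw, T, qs, As, ts, ramp_time,
):
    alpha = 4.0 / 3.0
    kr = -8.0 * np.pi * nu
    ncell = A.shape[0]
    Ap = np.empty(ncell)
    qp = np.empty(ncell)
    store_row = 0
    start_store = total - nsteps_cycle
    for step in range(total):
        tabs = step * dt
        t = tabs % T
        # inlet flow (half-cosine start-up ramp)
        qin = np.interp(t, tw, qw)
        if ramp_time > 0.0 and tabs < ramp_time:
            qin *= 0.5 * (1.0 - np.cos(np.pi * tabs / ramp_time))

        # --- predictor (forward differences) -------------------------
        for s in range(seg_start.shape[0]):
            i0 = seg_start[s]
            i1 = seg_end[s]
            for i in range(i0, i1 - 1):
                f1a = q[i]
                f1b = q[i + 1]
                f2a = alpha * q[i] * q[i] / A[i]
                f2b = alpha * q[i + 1] * q[i + 1] / A[i + 1]
                pa = _tube_pressure(A[i], A0[i], G[i])
                pb = _tube_pressure(A[i + 1], A0[i + 1], G[i + 1])
                inv = dt / ds[s]
                Ap[i] = A[i] - inv * (f1b - f1a)
                qp[i] = (
                    q[i]
                    - inv * (f2b - f2a)
                    - inv * (A[i] / rho) * (pb - pa)
                    + dt * kr * q[i] / A[i]
                )
            Ap[i1 - 1] = A[i1 - 1]
            qp[i1 - 1] = q[i1 - 1]
        _apply_bc(Ap, qp, A, q, A0, G, c0, rho, qin, seg_start, seg_end,
                  junc, leaves)
        # --- corrector (backward differences) ------------------------
        for s in range(seg_start.shape[0]):
            i0 = seg_start[s]
            i1 = seg_end[s]
            for i in range(i1 - 2, i0, -1):
                f1a = qp[i - 1]
                f1b = qp[i]
                f2a = alpha * qp[i - 1] * qp[i - 1] / Ap[i - 1]
                f2b = alpha * qp[i] * qp[i] / Ap[i]
                pa = _tube_pressure(Ap[i - 1], A0[i - 1], G[i - 1])
                pb = _tube_pressure(Ap[i], A0[i], G[i])
                inv = dt / ds[s]
                Anew = 0.5 * (
                    A[i] + Ap[i] - inv * (f1b - f1a)
                )
                qnew = 0.5 * (
                    q[i] + qp[i]
                    - inv * (f2b - f2a)
                    - inv * (Ap[i] / rho) * (pb - pa)
                    + dt * kr * qp[i] / Ap[i]
                )
                A[i] = Anew
                q[i] = qnew
            # first interior handled by BC pass below
        _apply_bc(A, q, Ap, qp, A0, G, c0, rho, qin, seg_start, seg_end,
                  junc, leaves)
        for i in range(ncell):
            if A[i] <= 0.25 * A0[i] or A[i] != A[i]:
                raise ValueError(
                    "1D area collapsed: wall stiffness too low or CFL failure"
                )
        if step >= start_store and (step - start_store) % store_every == 0:
            if store_row < qs.shape[0]:
                for i in range(ncell):
                    qs[store_row, i] = q[i]
                    As[store_row, i] = A[i]
                ts[store_row] = step * dt
                store_row += 1
    return 0


@njit(cache=True)
def _apply_bc(A, q, Aold, qold, A0, G, c0, rho, qin, seg_start, seg_end,
              junc, leaves):
    # inlet: prescribed flow, pressure from the backward characteristic
    i0 = seg_start[0]
    uin = qin / A0[i0]
    wminus = qold[i0 + 1] / Aold[i0 + 1] - _tube_pressure(
        Aold[i0 + 1], A0[i0 + 1], G[i0 + 1]
    ) / (rho * c0[i0])
    pin = rho * c0[i0] * (uin - wminus)
    root = 1.0 - pin / G[i0]
    if root < 0.1:
        root = 0.1
    A[i0] = A0[i0] / (root * root)
    q[i0] = uin * A[i0]

    # leaves: p = 0 (A = A0), flow from the forward characteristic
    for li in range(leaves.shape[0]):
        s = leaves[li]
        iN = seg_end[s] - 1
        wplus = qold[iN - 1] / Aold[iN - 1] + _tube_pressure(
            Aold[iN - 1], A0[iN - 1], G[iN - 1]
        ) / (rho * c0[iN])
        A[iN] = A0[iN]
        q[iN] = wplus * A0[iN]

    # junctions: continuity of flow and total pressure (Newton, 3 unknowns)
    for ji in range(junc.shape[0]):
        p_seg = junc[ji, 0]
        k1 = junc[ji, 1]
        k2 = junc[ji, 2]
        nk = junc[ji, 3]
        iP = seg_end[p_seg] - 1
        i1 = seg_start[k1]
        i2 = seg_start[k2]
        cP = c0[iP]
        c1 = c0[i1]
        c2 = c0[i2]
        wP = qold[iP - 1] / Aold[iP - 1] + _tube_pressure(
            Aold[iP - 1], A0[iP - 1], G[iP - 1]
        ) / (rho * cP)
        w1 = qold[i1 + 1] / Aold[i1 + 1] - _tube_pressure(
            Aold[i1 + 1], A0[i1 + 1], G[i1 + 1]
        ) / (rho * c1)
        if nk == 1:
            # pass-through junction: two-point coupling
            # unknowns uP, u1 with pP = rho cP (wP - uP), p1 = rho c1 (u1 - w1)
            uP = qold[iP] / Aold[iP]
            u1 = qold[i1] / Aold[i1]
            for _ in range(4):
                pP = rho * cP * (wP - uP)
                p1 = rho * c1 * (u1 - w1)
                F1 = A0[iP] * uP - A0[i1] * u1
                F2 = pP + 0.5 * rho * uP * uP - p1 - 0.5 * rho * u1 * u1
                J11 = A0[iP]
                J12 = -A0[i1]
                J21 = -rho * cP + rho * uP
                J22 = -rho * c1 - rho * u1
                det = J11 * J22 - J12 * J21
                duP = -(F1 * J22 - F2 * J12) / det
                du1 = -(J11 * F2 - J21 * F1) / det
                uP += duP
                u1 += du1
            _set_iface(A, q, iP, A0[iP], G[iP], rho * cP * (wP - uP), uP, G)
            _set_iface(A, q, i1, A0[i1], G[i1], rho * c1 * (u1 - w1), u1, G)
            continue
        w2 = qold[i2 + 1] / Aold[i2 + 1] - _tube_pressure(
            Aold[i2 + 1], A0[i2 + 1], G[i2 + 1]
        ) / (rho * c2)
        uP = qold[iP] / Aold[iP]
        u1 = qold[i1] / Aold[i1]
        u2 = qold[i2] / Aold[i2]
        for _ in range(4):
            pP = rho * cP * (wP - uP)
            p1 = rho * c1 * (u1 - w1)
            p2 = rho * c2 * (u2 - w2)
            F1 = A0[iP] * uP - A0[i1] * u1 - A0[i2] * u2
            F2 = pP + 0.5 * rho * uP * uP - p1 - 0.5 * rho * u1 * u1
            F3 = pP + 0.5 * rho * uP * uP - p2 - 0.5 * rho * u2 * u2
            a11 = A0[iP]
            a12 = -A0[i1]
            a13 = -A0[i2]
            a21 = -rho * cP + rho * uP
            a22 = -rho * c1 - rho * u1
            a23 = 0.0
            a31 = -rho * cP + rho * uP
            a32 = 0.0
            a33 = -rho * c2 - rho * u2
            det = (
                a11 * (a22 * a33 - a23 * a32)
                - a12 * (a21 * a33 - a23 * a31)
                + a13 * (a21 * a32 - a22 * a31)
            )
            b1 = -F1
            b2 = -F2
            b3 = -F3
            duP = (
                b1 * (a22 * a33 - a23 * a32)
                - a12 * (b2 * a33 - a23 * b3)
                + a13 * (b2 * a32 - a22 * b3)
            ) / det
            du1 = (
                a11 * (b2 * a33 - a23 * b3)
                - b1 * (a21 * a33 - a23 * a31)
                + a13 * (a21 * b3 - b2 * a31)
            ) / det
            du2 = (
                a11 * (a22 * b3 - b2 * a32)
                - a12 * (a21 * b3 - b2 * a31)
                + b1 * (a21 * a32 - a22 * a31)
            ) / det
            uP += duP
            u1 += du1
            u2 += du2
        _set_iface(A, q, iP, A0[iP], G[iP], rho * cP * (wP - uP), uP, G)
        _set_iface(A, q, i1, A0[i1], G[i1], rho * c1 * (u1 - w1), u1, G)
        _set_iface(A, q, i2, A0[i2], G[i2], rho * c2 * (u2 - w2), u2, G)


@njit(cache=True)
def _set_iface(A, q, i, A0i, Gi, p, u, G):
    root = 1.0 - p / Gi
    if root < 0.1:
        root = 0.1
    A[i] = A0i / (root * root)
    q[i] = u * A[i]
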