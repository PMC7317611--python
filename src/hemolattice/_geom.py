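"""Low-level triangle-mesh geometry kernels (numba).

Exact point-to-triangle distance with angle-weighted pseudo-normal signs
(Baerentzen & Aanaes) and Moller-Trumbore segment/triangle intersection,
driven by a uniform triangle-bucket grid.  These primitives back the
narrow-band signed-distance voxelizer.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "pseudo_normals",
    "band_distance",
    "TriangleBuckets",
    "segment_hits",
    "closest_triangles",
]


@njit(cache=True)
def _closest_point_triangle(p, a, b, c):
    """Closest point on triangle abc to p (Ericson, real-time collision).

    Returns (cp, region) with region 0 face, 1/2/3 vertices a/b/c,
    4/5/6 edges ab/ac/bc.
    """
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = ab[0] * ap[0] + ab[1] * ap[1] + ab[2] * ap[2]
    d2 = ac[0] * ap[0] + ac[1] * ap[1] + ac[2] * ap[2]
    if d1 <= 0.0 and d2 <= 0.0:
        return a.copy(), 1
    bp = p - b
    d3 = ab[0] * bp[0] + ab[1] * bp[1] + ab[2] * bp[2]
    d4 = ac[0] * bp[0] + ac[1] * bp[1] + ac[2] * bp[2]
    if d3 >= 0.0 and d4 <= d3:
        return b.copy(), 2
    vc = d1 * d4 - d3 * d2
    if vc <= 0.0 and d1 >= 0.0 and d3 <= 0.0:
        v = d1 / (d1 - d3)
        return a + v * ab, 4
    cp_ = p - c
    d5 = ab[0] * cp_[0] + ab[1] * cp_[1] + ab[2] * cp_[2]
    d6 = ac[0] * cp_[0] + ac[1] * cp_[1] + ac[2] * cp_[2]
    if d6 >= 0.0 and d5 <= d6:
        return c.copy(), 3
    vb = d5 * d2 - d1 * d6
    if vb <= 0.0 and d2 >= 0.0 and d6 <= 0.0:
        w = d2 / (d2 - d6)
        return a + w * ac, 5
    va = d3 * d6 - d5 * d4
    if va <= 0.0 and (d4 - d3) >= 0.0 and (d5 - d6) >= 0.0:
        w = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        return b + w * (c - b), 6
    denom = 1.0 / (va + vb + vc)
    v = vb * denom
    w = vc * denom
    return a + v * ab + w * ac, 0


def pseudo_normals(vertices: np.ndarray, faces: np.ndarray):
    """Face, edge and angle-weighted vertex pseudo-normals.

    Returns (face_n, edge_n, vert_n) where ``edge_n[t, k]`` is the normal of
    the edge opposite ordering ``k`` in (ab, ac, bc) of triangle ``t``.
    Requires a watertight, consistently oriented mesh.
    """
    v = np.asarray(vertices, dtype=np.float64)
    f = np.asarray(faces, dtype=np.int64)
    tri = v[f]
    fn = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    norms = np.linalg.norm(fn, axis=1)
    fn = fn / np.maximum(norms, 1e-300)[:, None]

    # edge normals: sum of the two adjacent face normals
    edges = {}
    for t in range(len(f)):
        for e in ((f[t, 0], f[t, 1]), (f[t, 0], f[t, 2]), (f[t, 1], f[t, 2])):
            key = (min(e), max(e))
            edges.setdefault(key, []).append(t)
    edge_n = np.zeros((len(f), 3, 3))
    for t in range(len(f)):
        for k, e in enumerate(
            ((f[t, 0], f[t, 1]), (f[t, 0], f[t, 2]), (f[t, 1], f[t, 2]))
        ):
            key = (min(e), max(e))
            for tt in edges[key]:
                edge_n[t, k] += fn[tt]
    nn = np.linalg.norm(edge_n, axis=2)
    edge_n /= np.maximum(nn, 1e-300)[:, :, None]

    # angle-weighted vertex normals
    vert_n = np.zeros_like(v)
    for k in range(3):
        p0 = tri[:, k]
        p1 = tri[:, (k + 1) % 3]
        p2 = tri[:, (k + 2) % 3]
        e1 = p1 - p0
        e2 = p2 - p0
        cosang = np.einsum("ij,ij->i", e1, e2) / np.maximum(
            np.linalg.norm(e1, axis=1) * np.linalg.norm(e2, axis=1), 1e-300
        )
        ang = np.arccos(np.clip(cosang, -1.0, 1.0))
        np.add.at(vert_n, f[:, k], ang[:, None] * fn)
    nn = np.linalg.norm(vert_n, axis=1)
    vert_n /= np.maximum(nn, 1e-300)[:, None]
    return fn, edge_n, vert_n


@njit(cache=True)
def band_distance(
    tri_verts,      # (nt, 3, 3)
    face_n, edge_n, vert_n, faces,
    origin, dx, shape,   # grid: node x = origin + idx*dx
    band,            # band half width (physical)
):
    """Signed distance and nearest triangle over a narrow band.

    Returns (phi, tid) flat arrays over the full grid; nodes outside the
    band keep ``phi = +inf`` and ``tid = -1``.  Sign is taken from the
    pseudo-normal of the closest feature (negative inside).  Ties between
    triangles at equal distance resolve to the lexicographically smallest
    closest-point feature so that triangle ordering cannot change results.
    """
    nx, ny, nz = shape
    n = nx * ny * nz
    dist2 = np.full(n, np.inf)
    tid = np.full(n, -1, dtype=np.int64)
    sign = np.ones(n)
    nt = tri_verts.shape[0]
    for t in range(nt):
        a = tri_verts[t, 0]
        b = tri_verts[t, 1]
        c = tri_verts[t, 2]
        lo0 = min(a[0], min(b[0], c[0])) - band
        hi0 = max(a[0], max(b[0], c[0])) + band
        lo1 = min(a[1], min(b[1], c[1])) - band
        hi1 = max(a[1], max(b[1], c[1])) + band
        lo2 = min(a[2], min(b[2], c[2])) - band
        hi2 = max(a[2], max(b[2], c[2])) + band
        i0 = max(0, int(np.ceil((lo0 - origin[0]) / dx)))
        i1 = min(nx - 1, int(np.floor((hi0 - origin[0]) / dx)))
        j0 = max(0, int(np.ceil((lo1 - origin[1]) / dx)))
        j1 = min(ny - 1, int(np.floor((hi1 - origin[1]) / dx)))
        k0 = max(0, int(np.ceil((lo2 - origin[2]) / dx)))
        k1 = min(nz - 1, int(np.floor((hi2 - origin[2]) / dx)))
        p = np.empty(3)
        for i in range(i0, i1 + 1):
            p[0] = origin[0] + i * dx
            for j in range(j0, j1 + 1):
                p[1] = origin[1] + j * dx
                for k in range(k0, k1 + 1):
                    p[2] = origin[2] + k * dx
                    cp, region = _closest_point_triangle(p, a, b, c)
                    d0 = p[0] - cp[0]
                    d1 = p[1] - cp[1]
                    d2 = p[2] - cp[2]
                    d2sum = d0 * d0 + d1 * d1 + d2 * d2
                    idx = (i * ny + j) * nz + k
                    best = dist2[idx]
                    tol = 1e-24 * dx * dx
                    if d2sum < best - tol or (
                        abs(d2sum - best) <= tol and t < tid[idx]
                    ):
                        # pick the pseudo-normal of the closest feature
                        if region == 0:
                            nrm = face_n[t]
                        elif region == 1:
                            nrm = vert_n[faces[t, 0]]
                        elif region == 2:
                            nrm = vert_n[faces[t, 1]]
                        elif region == 3:
                            nrm = vert_n[faces[t, 2]]
                        else:
                            nrm = edge_n[t, region - 4]
                        dot = d0 * nrm[0] + d1 * nrm[1] + d2 * nrm[2]
                        dist2[idx] = d2sum
                        tid[idx] = t
                        sign[idx] = 1.0 if dot >= 0.0 else -1.0
    phi = np.sqrt(dist2) * sign
    return phi, tid


class TriangleBuckets:
    """Uniform spatial hash over triangle bounding boxes."""

    def __init__(self, tri_verts: np.ndarray, cell: float, pad: float = 0.0):
        self.tri_verts = np.ascontiguousarray(tri_verts, dtype=np.float64)
        lo = tri_verts.min(axis=(0, 1)) - pad - cell
        hi = tri_verts.max(axis=(0, 1)) + pad + cell
        self.origin = lo
        self.cell = cell
        self.shape = np.maximum(
            np.ceil((hi - lo) / cell).astype(np.int64) + 1, 1
        )
        counts, starts, items = _build_buckets(
            self.tri_verts, lo, cell, self.shape
        )
        self.starts = starts
        self.items = items

    def segment_hits(self, p0, p1, priority=None):
        """First intersection of segments p0->p1 with the mesh.

        Returns (hit_t, hit_tid) arrays aligned with the segments; ``t`` is
        the smallest intersection parameter in [0, 1] (+inf if none).
        Numerically tied hits (a segment grazing a shared edge) resolve to
        the triangle with the larger ``priority`` value, independent of
        triangle ordering.
        """
        if priority is None:
            priority = np.zeros(len(self.tri_verts), dtype=np.int64)
        return segment_hits(
            np.ascontiguousarray(p0, dtype=np.float64),
            np.ascontiguousarray(p1, dtype=np.float64),
            self.tri_verts,
            self.origin,
            self.cell,
            self.shape,
            self.starts,
            self.items,
            np.ascontiguousarray(priority, dtype=np.int64),
        )


@njit(cache=True)
def _build_buckets(tri_verts, origin, cell, shape):
    nt = tri_verts.shape[0]
    nx, ny, nz = shape[0], shape[1], shape[2]
    ncell = nx * ny * nz
    counts = np.zeros(ncell, dtype=np.int64)
    bounds = np.empty((nt, 6), dtype=np.int64)
    for t in range(nt):
        for a in range(3):
            lo = min(tri_verts[t, 0, a], min(tri_verts[t, 1, a], tri_verts[t, 2, a]))
            hi = max(tri_verts[t, 0, a], max(tri_verts[t, 1, a], tri_verts[t, 2, a]))
            b0 = int((lo - origin[a]) / cell)
            b1 = int((hi - origin[a]) / cell)
            bounds[t, 2 * a] = max(0, b0)
            bounds[t, 2 * a + 1] = min(shape[a] - 1, b1)
        for i in range(bounds[t, 0], bounds[t, 1] + 1):
            for j in range(bounds[t, 2], bounds[t, 3] + 1):
                for k in range(bounds[t, 4], bounds[t, 5] + 1):
                    counts[(i * ny + j) * nz + k] += 1
    starts = np.zeros(ncell + 1, dtype=np.int64)
    for i in range(ncell):
        starts[i + 1] = starts[i] + counts[i]
    items = np.empty(starts[ncell], dtype=np.int64)
    fill = np.zeros(ncell, dtype=np.int64)
    for t in range(nt):
        for i in range(bounds[t, 0], bounds[t, 1] + 1):
            for j in range(bounds[t, 2], bounds[t, 3] + 1):
                for k in range(bounds[t, 4], bounds[t, 5] + 1):
                    cidx = (i * ny + j) * nz + k
                    items[starts[cidx] + fill[cidx]] = t
                    fill[cidx] += 1
    return counts, starts, items


@njit(cache=True)
def _seg_tri(p0, d, a, b, c, eps):
    """Moller-Trumbore; returns t in segment parameter or -1."""
    e1x = b[0] - a[0]
    e1y = b[1] - a[1]
    e1z = b[2] - a[2]
    e2x = c[0] - a[0]
    e2y = c[1] - a[1]
    e2z = c[2] - a[2]
    px = d[1] * e2z - d[2] * e2y
    py = d[2] * e2x - d[0] * e2z
    pz = d[0] * e2y - d[1] * e2x
    det = e1x * px + e1y * py + e1z * pz
    if abs(det) < eps:
        return -1.0
    inv = 1.0 / det
    tx = p0[0] - a[0]
    ty = p0[1] - a[1]
    tz = p0[2] - a[2]
    u = (tx * px + ty * py + tz * pz) * inv
    if u < -1e-9 or u > 1.0 + 1e-9:
        return -1.0
    qx = ty * e1z - tz * e1y
    qy = tz * e1x - tx * e1z
    qz = tx * e1y - ty * e1x
    v = (d[0] * qx + d[1] * qy + d[2] * qz) * inv
    if v < -1e-9 or u + v > 1.0 + 1e-9:
        return -1.0
    return (e2x * qx + e2y * qy + e2z * qz) * inv


@njit(cache=True)
def segment_hits(p0, p1, tri_verts, origin, cell, shape, starts, items, prio):
    nseg = p0.shape[0]
    ny, nz = shape[1], shape[2]
    hit_t = np.full(nseg, np.inf)
    hit_tid = np.full(nseg, -1, dtype=np.int64)
    t_tol = 1e-9
    for s in range(nseg):
        d = p1[s] - p0[s]
        seglen = np.sqrt(d[0] ** 2 + d[1] ** 2 + d[2] ** 2)
        eps = 1e-14 * max(seglen, 1e-30) ** 3
        # visit buckets covered by the segment AABB (segments are ~1 cell)
        b = np.empty(6, dtype=np.int64)
        for a in range(3):
            lo = min(p0[s, a], p1[s, a])
            hi = max(p0[s, a], p1[s, a])
            b[2 * a] = max(0, int((lo - origin[a]) / cell))
            b[2 * a + 1] = min(shape[a] - 1, int((hi - origin[a]) / cell))
        for i in range(b[0], b[1] + 1):
            for j in range(b[2], b[3] + 1):
                for k in range(b[4], b[5] + 1):
                    cidx = (i * ny + j) * nz + k
                    for ii in range(starts[cidx], starts[cidx + 1]):
                        t = items[ii]
                        tpar = _seg_tri(
                            p0[s], d,
                            tri_verts[t, 0], tri_verts[t, 1], tri_verts[t, 2],
                            eps,
                        )
                        if tpar >= -1e-9 and tpar <= 1.0 + 1e-9:
                            take = False
                            if tpar < hit_t[s] - t_tol:
                                take = True
                            elif tpar <= hit_t[s] + t_tol:
                                # grazing tie: higher priority wins, then
                                # lower triangle id for determinism
                                old = hit_tid[s]
                                if old < 0 or prio[t] > prio[old] or (
                                    prio[t] == prio[old] and t < old
                                ):
                                    take = True
                            if take:
                                if tpar < hit_t[s]:
                                    hit_t[s] = tpar
                                hit_tid[s] = t
    return hit_t, hit_tid


@njit(cache=True)
def closest_triangles(points, tri_verts, origin, cell, shape, starts, items):
    """Nearest triangle id + distance for query points via ring search."""
    npts = points.shape[0]
    ny, nz = shape[1], shape[2]
    out_d = np.full(npts, np.inf)
    out_t = np.full(npts, -1, dtype=np.int64)
    for s in range(npts):
        ci = int((points[s, 0] - origin[0]) / cell)
        cj = int((points[s, 1] - origin[1]) / cell)
        ck = int((points[s, 2] - origin[2]) / cell)
        for ring in range(0, max(shape[0], max(ny, nz)) + 1):
            found = out_t[s] >= 0
            # once a hit exists, search one extra ring then stop
            if found and ring > 0 and out_d[s] <= (ring - 1) * cell:
                break
            i0 = max(0, ci - ring)
            i1 = min(shape[0] - 1, ci + ring)
            j0 = max(0, cj - ring)
            j1 = min(ny - 1, cj + ring)
            k0 = max(0, ck - ring)
            k1 = min(nz - 1, ck + ring)
            for i in range(i0, i1 + 1):
                for j in range(j0, j1 + 1):
                    for k in range(k0, k1 + 1):
                        on_shell = (
                            i == i0 or i == i1 or j == j0 or j == j1
                            or k == k0 or k == k1
                        )
                        if ring > 0 and not on_shell:
                            continue
                        cidx = (i * ny + j) * nz + k
                        for ii in range(starts[cidx], starts[cidx + 1]):
                            t = items[ii]
                            cp, _ = _closest_point_triangle(
                                points[s],
                                tri_verts[t, 0],
                                tri_verts[t, 1],
                                tri_verts[t, 2],
                            )
                            dd = np.sqrt(
                                (points[s, 0] - cp[0]) ** 2
                                + (points[s, 1] - cp[1]) ** 2
                                + (points[s, 2] - cp[2]) ** 2
                            )
                            if dd < out_d[s] or (dd == out_d[s] and t < out_t[s]):
                                out_d[s] = dd
                                out_t[s] = t
    return out_d, out_t
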