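"""Level-set voxelization, node labeling and link fractions."""

import numpy as np
import pytest

from hemolattice.fixtures import make_tube
from hemolattice.voxelize import (
    LABEL_BULK,
    LABEL_INLET,
    LABEL_OUTLET0,
    LABEL_SOLID,
    LABEL_WALL,
    GeometryError,
    TAG_INLET,
    TAG_WALL,
    TaggedSurfaceMesh,
    label_nodes,
    link_fraction,
    voxelize,
)

R, L = 2e-3, 12e-3
DX = 2 * R / 15


class TestLinkFraction:
    @pytest.mark.parametrize(
        "phi_x, phi_n, expected",
        [(-0.3, 0.3, 0.5), (0.0, 1.0, 0.0), (-0.2, 0.6, 0.25)],
    )
    def test_closed_form(self, phi_x, phi_n, expected):
        assert link_fraction(phi_x, phi_n) == pytest.approx(expected)

    def test_rejects_non_crossing(self):
        with pytest.raises(ValueError):
            link_fraction(0.1, 0.2)
        with pytest.raises(ValueError):
            link_fraction(-0.1, -0.2)

    def test_range(self):
        rng = np.random.default_rng(0)
        px = -rng.uniform(0.0, 1.0, 100)
        pn = rng.uniform(1e-9, 1.0, 100)
        q = link_fraction(px, pn)
        assert np.all((q >= 0) & (q < 1))


class TestSignedDistance:
    def test_band_matches_analytic_cylinder(self, tube_mesh, labeled_tube):
        grid = labeled_tube
        idx = np.argwhere(np.abs(grid.phi) <= grid.band)
        pts = grid.origin + idx * grid.dx
        # away from the caps, phi is the distance to the lateral surface
        sel = (pts[:, 2] > 1.5e-3) & (pts[:, 2] < L - 1.5e-3)
        r = np.hypot(pts[sel, 0], pts[sel, 1])
        sag = R * (1 - np.cos(np.pi / 48))  # faceting tolerance
        err = np.abs(grid.phi[tuple(idx[sel].T)] - (r - R))
        assert err.max() <= sag * 1.5

    def test_point_on_surface_has_zero_distance(self, tube_mesh):
        """The signed point-to-triangle distance vanishes on the surface."""
        from hemolattice import _geom

        tri_verts = np.ascontiguousarray(
            tube_mesh.vertices[tube_mesh.faces], dtype=np.float64
        )
        fn, en, vn = _geom.pseudo_normals(tube_mesh.vertices, tube_mesh.faces)
        # grid with one node exactly at a surface vertex
        v = tube_mesh.vertices[0]
        phi, _ = _geom.band_distance(
            tri_verts, fn, en, vn, tube_mesh.faces,
            np.asarray(v, dtype=np.float64), DX,
            np.asarray([1, 1, 1], dtype=np.int64), 2 * DX,
        )
        assert abs(phi[0]) == pytest.approx(0.0, abs=1e-12)

    def test_flush_caps_sit_at_half_link(self, tube_mesh, labeled_tube):
        """Axis-aligned caps land midway between node planes (q = 1/2)."""
        grid = labeled_tube
        frac = (-grid.origin[2]) / grid.dx
        assert frac - np.floor(frac) == pytest.approx(0.5, abs=1e-9)

    def test_sign_matches_ray_casting_oracle(self, tube_mesh, labeled_tube):
        """Independent point-in-mesh test by brute-force ray casting."""
        grid = labeled_tube
        rng = np.random.default_rng(1)
        ii = rng.integers(0, grid.shape[0], 60)
        jj = rng.integers(0, grid.shape[1], 60)
        kk = rng.integers(0, grid.shape[2], 60)
        pts = grid.origin + np.stack([ii, jj, kk], axis=1) * grid.dx
        tri = tube_mesh.vertices[tube_mesh.faces]
        direction = np.array([0.37, 0.41, 0.83])
        direction /= np.linalg.norm(direction)
        for p, i, j, k in zip(pts, ii, jj, kk):
            crossings = _count_crossings(p, direction, tri)
            inside = crossings % 2 == 1
            assert (grid.phi[i, j, k] <= 0) == inside

    def test_non_watertight_mesh_rejected(self, tube_mesh):
        broken = TaggedSurfaceMesh(
            vertices=tube_mesh.vertices,
            faces=tube_mesh.faces[:-5],
            face_tags=tube_mesh.face_tags[:-5],
        )
        with pytest.raises(GeometryError, match="watertight"):
            voxelize(broken, DX)

    def test_volume_estimate_converges_monotonically(self, tube_mesh):
        exact = np.pi * R**2 * L
        errs = []
        for dx in (R / 2.5, R / 5):
            vol = voxelize(tube_mesh, dx).interior_volume()
            errs.append(abs(vol - exact) / exact)
        assert errs[1] < errs[0]


def _count_crossings(origin, direction, tri):
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    e1, e2 = v1 - v0, v2 - v0
    h = np.cross(direction, e2)
    a = np.einsum("ij,ij->i", e1, h)
    ok = np.abs(a) > 1e-30
    f = np.zeros_like(a)
    f[ok] = 1.0 / a[ok]
    s = origin - v0
    u = f * np.einsum("ij,ij->i", s, h)
    qv = np.cross(s, e1)
    v = f * (qv @ direction)
    t = f * np.einsum("ij,ij->i", e2, qv)
    hit = ok & (u >= 0) & (u <= 1) & (v >= 0) & (u + v <= 1) & (t > 1e-12)
    return int(hit.sum())


class TestLabeling:
    def test_counts_match_brute_force_classifier(self, tube_mesh):
        """Exhaustive per-node per-link reclassification on a coarse grid."""
        from hemolattice.lattice import build_d3q19

        dx = R / 3
        grid = label_nodes(voxelize(tube_mesh, dx), mesh=tube_mesh)
        lat = build_d3q19()
        tags = tube_mesh.tag_codes()
        tri = tube_mesh.vertices[tube_mesh.faces]
        shape = grid.shape
        expected = np.zeros(shape, dtype=int)
        for i in range(shape[0]):
            for j in range(shape[1]):
                for k in range(shape[2]):
                    expected[i, j, k] = _classify(
                        grid, lat, tri, tags, np.array([i, j, k])
                    )
        assert np.array_equal(expected, grid.labels)

    def test_interior_node_is_bulk(self, labeled_tube):
        grid = labeled_tube
        ci = grid.shape[0] // 2
        kz = grid.shape[2] // 2
        assert grid.labels[ci, grid.shape[1] // 2, kz] == LABEL_BULK

    def test_corner_nodes_prefer_openings(self, labeled_tube, tube_mesh):
        """Nodes with both opening and wall crossings take the opening tag."""
        grid = labeled_tube
        both = 0
        flat_labels = grid.labels.ravel()
        for row in np.argwhere(
            (grid.link_tag >= 1).any(axis=1) & (grid.link_tag == 0).any(axis=1)
        ).ravel():
            both += 1
            assert flat_labels[row] >= LABEL_INLET
        assert both > 0  # the tube rim provides genuine corner nodes

    def test_triangle_permutation_invariance(self, tube_mesh):
        rng = np.random.default_rng(4)
        perm = rng.permutation(len(tube_mesh.faces))
        shuffled = TaggedSurfaceMesh(
            vertices=tube_mesh.vertices,
            faces=tube_mesh.faces[perm],
            face_tags=tube_mesh.face_tags[perm],
        )
        dx = R / 3
        a = label_nodes(voxelize(tube_mesh, dx), mesh=tube_mesh)
        b = label_nodes(voxelize(shuffled, dx), mesh=shuffled)
        assert np.array_equal(a.labels, b.labels)

    def test_opening_nodes_near_tagged_triangles(self, labeled_tube, tube_mesh):
        from hemolattice._geom import _closest_point_triangle

        grid = labeled_tube
        for label, tag in ((LABEL_INLET, "inlet"), (LABEL_OUTLET0, "outlet_0")):
            nodes = np.argwhere(grid.labels == label)
            pts = grid.origin + nodes * grid.dx
            tri = tube_mesh.vertices[
                tube_mesh.faces[tube_mesh.faces_with_tag(tag)]
            ]
            for p in pts[:: max(1, len(pts) // 40)]:
                d = min(
                    np.linalg.norm(
                        p - _closest_point_triangle(p, t[0], t[1], t[2])[0]
                    )
                    for t in tri
                )
                assert d <= 2.0 * grid.dx

    def test_q_defined_exactly_on_crossing_links(self, labeled_tube):
        grid = labeled_tube
        has_q = np.isfinite(grid.q)
        has_tag = grid.link_tag >= 0
        assert np.array_equal(has_q, has_tag)
        q = grid.q[has_q]
        assert np.all((q >= 0) & (q <= 1))


def _classify(grid, lat, tri, tags, ijk):
    shape = grid.shape
    phi = grid.phi
    if phi[tuple(ijk)] > 0:
        return LABEL_SOLID
    p0 = grid.origin + ijk * grid.dx
    best = LABEL_BULK
    hit_wall = False
    hit_open = None
    for i in range(1, 19):
        tgt = ijk + lat.c[i]
        if np.any(tgt < 0) or np.any(tgt >= shape):
            continue
        if phi[tuple(tgt)] <= 0:
            continue
        p1 = grid.origin + tgt * grid.dx
        code = _first_hit_tag(p0, p1, tri, tags)
        if code is None:
            continue
        if code == TAG_WALL:
            hit_wall = True
        else:
            if hit_open is None or code < hit_open:
                hit_open = code
    if hit_open is not None:
        if hit_open == TAG_INLET:
            return LABEL_INLET
        return LABEL_OUTLET0 + hit_open - 2
    if hit_wall:
        return LABEL_WALL
    return best


def _first_hit_tag(p0, p1, tri, tags):
    d = p1 - p0
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    e1, e2 = v1 - v0, v2 - v0
    h = np.cross(d, e2)
    a = np.einsum("ij,ij->i", e1, h)
    ok = np.abs(a) > 1e-30
    f = np.zeros_like(a)
    f[ok] = 1.0 / a[ok]
    s = p0 - v0
    u = f * np.einsum("ij,ij->i", s, h)
    qv = np.cross(s, e1)
    v = f * (qv @ d)
    t = f * np.einsum("ij,ij->i", e2, qv)
    hit = ok & (u >= -1e-9) & (v >= -1e-9) & (u + v <= 1 + 1e-9)
    hit &= (t >= -1e-9) & (t <= 1 + 1e-9)
    if not hit.any():
        return None
    k = np.flatnonzero(hit)[np.argmin(t[hit])]
    return int(tags[k])
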