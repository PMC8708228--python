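"""Mesh container, STL I/O and geometric query tests."""

import numpy as np
import pytest
import trimesh as _trimesh
from trimesh.proximity import closest_point_naive

from mandiblefit.mesh import (
    TriangleMesh,
    RigidTransform,
    StlParseError,
    DegenerateGeometryError,
    ClosestPointIndex,
    read_stl,
    write_stl,
    read_landmarks,
    write_landmarks,
    closest_point,
    signed_distance,
    kabsch,
    apply_transform,
    mirror_sagittal,
    LandmarkSet,
)

ASCII_CUBE = None  # built from the cube fixture below


def _rotz(deg):
    a = np.deg2rad(deg)
    return np.array(
        [[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]]
    )


# ---------------------------------------------------------------------------
# STL I/O
# ---------------------------------------------------------------------------


class TestStlIO:
    def test_ascii_cube_welds_to_shared_vertices(self, cube_mesh, tmp_path):
        path = tmp_path / "cube.stl"
        write_stl(cube_mesh, path, mode="ascii")
        mesh = read_stl(path)
        assert mesh.n_vertices == 8
        assert mesh.n_faces == 12
        mesh.validate(strict=True)

    def test_binary_roundtrip_identity(self, cube_mesh, tmp_path):
        p1, p2 = tmp_path / "a.stl", tmp_path / "b.stl"
        write_stl(cube_mesh, p1, mode="binary")
        m1 = read_stl(p1)
        write_stl(m1, p2, mode="binary")
        m2 = read_stl(p2)
        np.testing.assert_array_equal(m1.vertices, m2.vertices)
        np.testing.assert_array_equal(m1.faces, m2.faces)
        # bit-stable after one write
        assert p1.read_bytes() == p2.read_bytes()

    def test_shared_edge_welding(self, tmp_path):
        # two triangles forming a square, 6 facet-vertex records -> 4 welded
        square = TriangleMesh(
            np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 0, 0], [1, 1, 0], [0, 1, 0]], float),
            np.array([[0, 1, 2], [3, 4, 5]]),
        )
        path = tmp_path / "sq.stl"
        write_stl(square, path, mode="ascii")
        mesh = read_stl(path)
        assert mesh.n_vertices == 4
        assert mesh.n_faces == 2

    def test_binary_single_triangle_size(self, tmp_path):
        tri = TriangleMesh(np.eye(3), np.array([[0, 1, 2]]))
        path = tmp_path / "tri.stl"
        write_stl(tri, path, mode="binary")
        assert path.stat().st_size == 84 + 50

    def test_refuses_empty_mesh(self, tmp_path):
        empty = TriangleMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))
        with pytest.raises(ValueError, match="0 facets"):
            write_stl(empty, tmp_path / "e.stl")

    def test_malformed_binary_names_byte_offset(self, cube_mesh, tmp_path):
        path = tmp_path / "bad.stl"
        write_stl(cube_mesh, path, mode="binary")
        raw = path.read_bytes()
        path.write_bytes(raw[:-10])  # truncate
        with pytest.raises(StlParseError, match="byte offset"):
            read_stl(path)

    def test_malformed_ascii_names_byte_offset(self, tmp_path):
        path = tmp_path / "bad.stl"
        path.write_text(
            "solid x\n facet normal 0 0 1\n outer loop\n"
            " vertex 0 0 zero\n vertex 1 0 0\n vertex 0 1 0\n"
            " endloop\n endfacet\nendsolid x\n"
        )
        with pytest.raises(StlParseError, match="byte offset"):
            read_stl(path)

    def test_trimesh_reads_our_binary(self, cube_mesh, tmp_path):
        # cross-check the binary dialect against an independent reader
        path = tmp_path / "cube.stl"
        write_stl(cube_mesh, path, mode="binary")
        tm = _trimesh.load(str(path), process=False)
        assert len(tm.faces) == 12


def test_landmark_csv_roundtrip(tmp_path):
    lms = LandmarkSet(["a", "b", "c"], np.arange(9.0).reshape(3, 3), ["left", "midline", "right"])
    path = tmp_path / "lms.csv"
    write_landmarks(lms, path)
    back = read_landmarks(path)
    assert back.names == lms.names
    assert back.sides == lms.sides
    np.testing.assert_allclose(back.points, lms.points)


# ---------------------------------------------------------------------------
# closest point / signed distance
# ---------------------------------------------------------------------------


class TestClosestPoint:
    def test_vertex_query_zero(self, cube_mesh):
        _, d, _ = closest_point(cube_mesh.vertices[3], cube_mesh)
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_height_above_triangle(self):
        tri = TriangleMesh(
            np.array([[0, 0, 0], [2, 0, 0], [0, 2, 0]], float), np.array([[0, 1, 2]])
        )
        foot, d, _ = closest_point(np.array([0.5, 0.5, 0.7]), tri)
        assert d == pytest.approx(0.7, abs=1e-12)
        np.testing.assert_allclose(foot, [0.5, 0.5, 0.0], atol=1e-12)

    def test_matches_bruteforce_oracle(self, template):
        rng = np.random.default_rng(42)
        q = rng.uniform(-80, 80, size=(1000, 3))
        index = ClosestPointIndex(template.mesh)
        _, dist, _ = index.query(q)
        tm = _trimesh.Trimesh(template.mesh.vertices, template.mesh.faces, process=False)
        _, d_oracle, _ = closest_point_naive(tm, q)
        np.testing.assert_allclose(dist, d_oracle, atol=1e-9)

    def test_signed_sign_and_magnitude(self, template):
        mesh = template.mesh
        vn = mesh.vertex_normals()
        idx = np.arange(0, mesh.n_vertices, 37)
        eps = 1e-3
        outside = mesh.vertices[idx] + eps * vn[idx]
        inside = mesh.vertices[idx] - eps * vn[idx]
        index = ClosestPointIndex(mesh)
        assert np.all(index.signed(outside) > 0)
        assert np.all(index.signed(inside) < 0)
        # |signed| equals the unsigned distance
        _, d, _ = index.query(outside)
        np.testing.assert_allclose(np.abs(index.signed(outside)), d, atol=1e-12)

    def test_on_surface_zero(self, cube_mesh):
        assert signed_distance(np.array([0.5, 0.5, 0.0]), cube_mesh) == pytest.approx(
            0.0, abs=1e-9
        )


# ---------------------------------------------------------------------------
# rigid transforms
# ---------------------------------------------------------------------------


class TestKabsch:
    def test_identity(self):
        pts = np.random.default_rng(0).normal(size=(10, 3))
        tf = kabsch(pts, pts)
        np.testing.assert_allclose(tf.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(tf.translation, 0, atol=1e-9)

    def test_recovers_known_transform(self):
        rng = np.random.default_rng(1)
        src = rng.normal(size=(20, 3))
        R = _rotz(30)
        t = np.array([1.0, 2.0, 3.0])
        tf = kabsch(src, src @ R.T + t)
        np.testing.assert_allclose(tf.rotation, R, atol=1e-9)
        np.testing.assert_allclose(tf.translation, t, atol=1e-9)
        tf.validate()

    def test_collinear_raises(self):
        src = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], float)
        with pytest.raises(DegenerateGeometryError):
            kabsch(src, src + 1.0)

    def test_no_reflection(self):
        rng = np.random.default_rng(2)
        src = rng.normal(size=(15, 3))
        dst = src.copy()
        dst[:, 0] *= -1  # reflected target
        tf = kabsch(src, dst)
        assert np.linalg.det(tf.rotation) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_left_invariance(self, seed):
        """Pre-transforming the source rigidly leaves the aligned positions
        unchanged."""
        rng = np.random.default_rng(seed)
        src = rng.normal(size=(12, 3))
        dst = rng.normal(size=(12, 3))
        Q = _rotz(77.0) @ np.array([[1, 0, 0], [0, 0, -1], [0, 1, 0]], float)
        u = np.array([-3.0, 0.5, 9.0])
        pre = src @ Q.T + u
        a1 = kabsch(src, dst).apply(src)
        a2 = kabsch(pre, dst).apply(pre)
        np.testing.assert_allclose(a1, a2, atol=1e-8)

    def test_weighted_prioritises_heavy_points(self):
        src = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        dst = src + np.array([0.5, 0, 0])
        dst[3] += np.array([0, 0, 0.4])  # outlier
        w = np.array([1e6, 1e6, 1e6, 1e-6])
        tf = kabsch(src, dst, w)
        np.testing.assert_allclose(tf.apply(src[:3]), dst[:3], atol=1e-5)


class TestTransformAlgebra:
    def test_compose_inverse_identity(self):
        tf = RigidTransform(_rotz(40), np.array([1.0, -2.0, 0.5]))
        ident = tf.compose(tf.inverse())
        np.testing.assert_allclose(ident.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(ident.translation, 0, atol=1e-12)

    def test_transform_then_inverse_on_mesh(self, cube_mesh):
        tf = RigidTransform(_rotz(25), np.array([0.3, 4.0, -1.0]))
        back = apply_transform(apply_transform(cube_mesh, tf), tf.inverse())
        np.testing.assert_allclose(back.vertices, cube_mesh.vertices, atol=1e-9)

    def test_mirror_twice_is_identity(self, cube_mesh):
        twice = mirror_sagittal(mirror_sagittal(cube_mesh))
        np.testing.assert_array_equal(twice.vertices, cube_mesh.vertices)
        np.testing.assert_array_equal(twice.faces, cube_mesh.faces)

    def test_mirror_preserves_orientation_and_signs(self, template):
        mirrored = mirror_sagittal(template.mesh)
        mirrored.validate(strict=True)
        # a point outside stays outside after mirroring both point and mesh
        vn = template.mesh.vertex_normals()
        p = template.mesh.vertices[10] + 0.5 * vn[10]
        d_orig = signed_distance(p, template.mesh)
        d_mirr = signed_distance(mirror_sagittal(p[None])[0], mirrored)
        assert d_orig == pytest.approx(d_mirr, abs=1e-9)
        assert d_orig > 0


class TestTransformProperties:
    """Property-based checks of rigid-transform closure."""

    from hypothesis import given, settings, strategies as st

    angles = st.floats(-np.pi, np.pi, allow_nan=False)
    coords = st.floats(-100, 100, allow_nan=False, allow_infinity=False)

    @given(a=angles, b=angles, c=angles, tx=coords, ty=coords, tz=coords)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_compose_inverse_closed(self, a, b, c, tx, ty, tz):
        from scipy.spatial.transform import Rotation

        tf = RigidTransform(
            Rotation.from_euler("xyz", [a, b, c]).as_matrix(), [tx, ty, tz]
        )
        tf.validate(atol=1e-12)
        ident = tf.compose(tf.inverse())
        ident.validate(atol=1e-9)
        np.testing.assert_allclose(ident.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(ident.translation, 0, atol=1e-9)

    @given(a=angles, b=angles, tx=coords, ty=coords)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_kabsch_recovers_arbitrary_pose(self, a, b, tx, ty):
        from scipy.spatial.transform import Rotation

        src = np.random.default_rng(0).normal(scale=10.0, size=(8, 3))
        R = Rotation.from_euler("xz", [a, b]).as_matrix()
        t = np.array([tx, ty, 1.0])
        rec = kabsch(src, src @ R.T + t)
        np.testing.assert_allclose(rec.rotation, R, atol=1e-8)
        np.testing.assert_allclose(rec.translation, t, atol=1e-7)


def test_validate_rejects_inconsistent_orientation():
    v = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], float)
    # second face wound the wrong way: shared edge (1,2) traversed twice in
    # the same direction
    bad = TriangleMesh(v, np.array([[0, 1, 2], [1, 2, 3]]))
    with pytest.raises(ValueError, match="orientation"):
        bad.validate(strict=True)
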