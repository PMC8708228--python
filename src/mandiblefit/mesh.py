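"""Triangle-mesh data model, STL I/O and geometric queries.

Everything downstream (shape modelling, plate design, virtual fitting) works
on millimetre-scale triangular surface meshes.  This module provides the
shared primitives: the :class:`TriangleMesh` container, STL reading/writing
with vertex welding, exact closest-point and signed-distance queries with a
KD-tree-accelerated index, the Kabsch rigid least-squares fit, and rigid
transform algebra.

Conventions (fixed package-wide):

* units are millimetres;
* vertex/face indices are 0-based;
* coordinates are right-handed and the sagittal mirror plane is ``x = 0``;
* positive signed distance means *outside* the surface (a gap between a
  plate and the bone), negative means penetration; edge and vertex feet are
  disambiguated with angle-weighted pseudonormals.
"""

from __future__ import annotations

import io
import struct
import csv
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "TriangleMesh",
    "RigidTransform",
    "LandmarkSet",
    "StlParseError",
    "DegenerateGeometryError",
    "read_stl",
    "write_stl",
    "read_landmarks",
    "write_landmarks",
    "closest_point",
    "signed_distance",
    "kabsch",
    "apply_transform",
    "mirror_sagittal",
    "ClosestPointIndex",
    "WELD_TOLERANCE_MM",
]

#: Default vertex-welding tolerance for STL facet soup, in mm.  Below CT
#: scanner precision, above float32 STL quantisation noise.
WELD_TOLERANCE_MM = 1e-6


class StlParseError(ValueError):
    """Malformed STL input; the message names the byte offset."""


class DegenerateGeometryError(ValueError):
    """Collinear / rank-deficient point configuration."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class TriangleMesh:
    """An indexed triangle surface.

    Parameters
    ----------
    vertices : (n, 3) float array, millimetres.
    faces : (m, 3) int array of 0-based vertex indices.
    vertex_labels : optional mapping label-name -> vertex-index array
        (region membership, keep-out flags, ...).
    """

    vertices: np.ndarray
    faces: np.ndarray
    vertex_labels: dict = field(default_factory=dict)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)

    # -- basic queries ------------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def face_normals(self) -> np.ndarray:
        """Unit normals per face (right-hand winding)."""
        tri = self.vertices[self.faces]
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return n / norm

    def face_areas(self) -> np.ndarray:
        tri = self.vertices[self.faces]
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return 0.5 * np.linalg.norm(n, axis=1)

    def vertex_normals(self) -> np.ndarray:
        """Angle-weighted per-vertex pseudonormals (unit)."""
        out = np.zeros_like(self.vertices)
        fn = self.face_normals()
        tri = self.vertices[self.faces]
        for corner in range(3):
            a = tri[:, corner]
            b = tri[:, (corner + 1) % 3]
            c = tri[:, (corner + 2) % 3]
            u = b - a
            v = c - a
            cosang = np.einsum("ij,ij->i", u, v) / (
                np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
            )
            ang = np.arccos(np.clip(cosang, -1.0, 1.0))
            np.add.at(out, self.faces[:, corner], fn * ang[:, None])
        norm = np.linalg.norm(out, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return out / norm

    def validate(self, strict: bool = True) -> None:
        """Check the container invariants; raise ``ValueError`` on violation.

        ``strict`` additionally requires consistent face orientation (each
        interior edge traversed once per direction) and positive-area faces.
        """
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= self.n_vertices):
            raise ValueError("face index out of range [0, n_vertices)")
        if np.any(
            (self.faces[:, 0] == self.faces[:, 1])
            | (self.faces[:, 1] == self.faces[:, 2])
            | (self.faces[:, 0] == self.faces[:, 2])
        ):
            raise ValueError("face with repeated vertex index")
        if strict:
            if np.any(self.face_areas() <= 0):
                raise ValueError("zero-area face after welding")
            # orientation: directed interior edges must be unique and each
            # undirected interior edge seen in both directions
            e = np.concatenate(
                [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
            )
            directed = set(map(tuple, e))
            if len(directed) != len(e):
                raise ValueError("inconsistent orientation: duplicated directed edge")

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(
            self.vertices.copy(),
            self.faces.copy(),
            {k: np.array(v).copy() for k, v in self.vertex_labels.items()},
        )

    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)


@dataclass
class RigidTransform:
    """Proper rigid motion ``x -> R x + t`` (no scaling, no reflection)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def validate(self, atol: float = 1e-9) -> None:
        err = np.abs(self.rotation.T @ self.rotation - np.eye(3)).max()
        if err > atol:
            raise ValueError(f"rotation not orthonormal (max error {err:g})")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("reflection is not a rigid transform")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self ∘ other``: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


@dataclass
class LandmarkSet:
    """Named, ordered anatomical points with a side tag per landmark."""

    names: list
    points: np.ndarray
    sides: list = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if self.sides is None:
            self.sides = ["midline"] * len(self.names)
        if len(set(self.names)) != len(self.names):
            raise ValueError("landmark names must be unique")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("landmark coordinates must be finite")

    def __len__(self) -> int:
        return len(self.names)

    def get(self, name: str) -> np.ndarray:
        return self.points[self.names.index(name)]

    def subset(self, names) -> "LandmarkSet":
        idx = [self.names.index(n) for n in names]
        return LandmarkSet(list(names), self.points[idx], [self.sides[i] for i in idx])


def read_landmarks(path) -> LandmarkSet:
    """Read a ``name,x,y,z,side`` CSV (header optional)."""
    names, pts, sides = [], [], []
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0].strip().lower() == "name":
                continue
            names.append(row[0].strip())
            pts.append([float(v) for v in row[1:4]])
            sides.append(row[4].strip() if len(row) > 4 else "midline")
    return LandmarkSet(names, np.array(pts), sides)


def write_landmarks(lms: LandmarkSet, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["name", "x", "y", "z", "side"])
        for name, p, side in zip(lms.names, lms.points, lms.sides):
            w.writerow([name, f"{p[0]:.9g}", f"{p[1]:.9g}", f"{p[2]:.9g}", side])


# ---------------------------------------------------------------------------
# STL I/O
# ---------------------------------------------------------------------------


def _weld(facet_vertices: np.ndarray, tol: float) -> tuple[np.ndarray, np.ndarray]:
    """Merge facet-soup vertices coincident within ``tol`` into shared ones."""
    keys = np.round(facet_vertices / tol).astype(np.int64)
    _, first, inverse = np.unique(keys, axis=0, return_index=True, return_inverse=True)
    return facet_vertices[first], inverse


def read_stl(path, weld_tolerance: float = WELD_TOLERANCE_MM, strict: bool = False) -> TriangleMesh:
    """Read a binary or ASCII STL file into a welded :class:`TriangleMesh`.

    Duplicated facet vertices are welded into shared vertices at
    ``weld_tolerance`` (mm); the facet count is preserved.  Raises
    :class:`StlParseError` naming the byte offset on malformed input.
    """
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < 15:
        raise StlParseError(f"{path}: file too short ({len(raw)} bytes) at byte offset 0")
    # An STL is ASCII iff it starts with 'solid' AND the byte layout does not
    # parse as binary (some binary exporters write 'solid' headers).
    is_ascii = raw.lstrip()[:5].lower() == b"solid"
    if is_ascii and len(raw) >= 84:
        (n_facets,) = struct.unpack_from("<I", raw, 80)
        if len(raw) == 84 + 50 * n_facets:
            is_ascii = False
    tris = _parse_ascii_stl(raw, path) if is_ascii else _parse_binary_stl(raw, path)
    vertices, inverse = _weld(tris.reshape(-1, 3), weld_tolerance)
    faces = inverse.reshape(-1, 3)
    mesh = TriangleMesh(vertices, faces)
    if strict:
        mesh.validate(strict=True)
    else:
        mesh.validate(strict=False)
    return mesh


def _parse_binary_stl(raw: bytes, path) -> np.ndarray:
    if len(raw) < 84:
        raise StlParseError(
            f"{path}: binary STL truncated before facet count at byte offset {len(raw)}"
        )
    (n_facets,) = struct.unpack_from("<I", raw, 80)
    expected = 84 + 50 * n_facets
    if len(raw) != expected:
        off = min(len(raw), expected)
        raise StlParseError(
            f"{path}: facet count {n_facets} implies {expected} bytes, "
            f"got {len(raw)} (mismatch at byte offset {off})"
        )
    body = np.frombuffer(raw, dtype=np.uint8, count=50 * n_facets, offset=84)
    rec = body.reshape(n_facets, 50)[:, :48].copy()
    floats = rec.view("<f4").reshape(n_facets, 12).astype(float)
    return floats[:, 3:12].reshape(n_facets, 3, 3)


def _parse_ascii_stl(raw: bytes, path) -> np.ndarray:
    text = raw.decode("ascii", errors="replace")
    tris = []
    current = []
    offset = 0
    for line in io.StringIO(text):
        stripped = line.strip()
        if stripped.startswith("vertex"):
            parts = stripped.split()
            if len(parts) != 4:
                raise StlParseError(
                    f"{path}: malformed vertex line at byte offset {offset}: {stripped!r}"
                )
            try:
                current.append([float(v) for v in parts[1:]])
            except ValueError as exc:
                raise StlParseError(
                    f"{path}: bad vertex coordinate at byte offset {offset}: {exc}"
                ) from exc
        elif stripped.startswith("endfacet"):
            if len(current) != 3:
                raise StlParseError(
                    f"{path}: facet with {len(current)} vertices at byte offset {offset}"
                )
            tris.append(current)
            current = []
        offset += len(line)
    if current:
        raise StlParseError(f"{path}: unterminated facet at byte offset {offset}")
    if not tris:
        raise StlParseError(f"{path}: no facets found at byte offset {offset}")
    return np.array(tris, dtype=float)


def write_stl(mesh: TriangleMesh, path, mode: str = "binary") -> None:
    """Write ``mesh`` as STL.  Binary mode is the 80-byte-header, uint32
    facet count, 50-byte little-endian facet dialect."""
    if mesh.n_faces == 0:
        raise ValueError("refusing to write an STL with 0 facets")
    if mode not in ("binary", "ascii"):
        raise ValueError(f"mode must be 'binary' or 'ascii', got {mode!r}")
    tri = mesh.vertices[mesh.faces]
    normals = mesh.face_normals()
    if mode == "binary":
        with open(path, "wb") as fh:
            fh.write(b"mandiblefit binary STL".ljust(80, b" "))
            fh.write(struct.pack("<I", mesh.n_faces))
            rec = np.zeros((mesh.n_faces, 50), dtype=np.uint8)
            block = np.concatenate([normals, tri.reshape(-1, 9)], axis=1).astype("<f4")
            rec[:, :48] = block.view(np.uint8).reshape(mesh.n_faces, 48)
            fh.write(rec.tobytes())
    else:
        with open(path, "w") as fh:
            fh.write("solid mandiblefit\n")
            for n, t in zip(normals, tri):
                fh.write(f"  facet normal {n[0]:.9e} {n[1]:.9e} {n[2]:.9e}\n")
                fh.write("    outer loop\n")
                for v in t:
                    fh.write(f"      vertex {v[0]:.9e} {v[1]:.9e} {v[2]:.9e}\n")
                fh.write("    endloop\n  endfacet\n")
            fh.write("endsolid mandiblefit\n")


# ---------------------------------------------------------------------------
# exact point-to-triangle distance (vectorised Ericson algorithm)
# ---------------------------------------------------------------------------


def _closest_on_triangles(p: np.ndarray, a: np.ndarray, b: np.ndarray, c: np.ndarray):
    """Closest point on triangle (a,b,c) to p, for stacked arrays of shape
    (k, 3).  Returns (foot points, squared distances)."""
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    foot = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    def assign(mask, value):
        m = mask & ~done
        foot[m] = value[m] if value.ndim == 2 else value
        done[m] = True

    assign((d1 <= 0) & (d2 <= 0), a)  # vertex a
    assign((d3 >= 0) & (d4 <= d3), b)  # vertex b
    assign((d6 >= 0) & (d5 <= d6), c)  # vertex c
    with np.errstate(divide="ignore", invalid="ignore"):
        t_ab = d1 / (d1 - d3)
        assign((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + t_ab[:, None] * ab)
        t_ac = d2 / (d2 - d6)
        assign((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + t_ac[:, None] * ac)
        t_bc = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        assign((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0), b + t_bc[:, None] * (c - b))
        denom = va + vb + vc
        v = vb / denom
        w = vc / denom
        assign(np.ones(len(p), dtype=bool), a + v[:, None] * ab + w[:, None] * ac)
    d2_sq = np.einsum("ij,ij->i", p - foot, p - foot)
    return foot, d2_sq


class ClosestPointIndex:
    """Exact closest-point queries accelerated by centroid KD-tree pruning.

    A KD-tree over triangle centroids yields an upper bound from the ``k``
    nearest candidate triangles; every triangle whose centroid lies within
    that bound plus the largest triangle circumradius is then tested exactly,
    so the result equals the brute-force minimum over all triangles.
    """

    def __init__(self, mesh: TriangleMesh, leaf_candidates: int = 8):
        if mesh.n_faces == 0:
            raise ValueError("cannot index an empty mesh")
        self.mesh = mesh
        tri = mesh.vertices[mesh.faces]
        self._tri = tri
        self._centroids = tri.mean(axis=1)
        self._radius = np.linalg.norm(tri - self._centroids[:, None, :], axis=2).max(axis=1)
        self._rmax = float(self._radius.max())
        self._tree = cKDTree(self._centroids)
        self._k = min(leaf_candidates, mesh.n_faces)
        # pseudonormal tables are built lazily for signed queries
        self._edge_normals = None
        self._vertex_normals = None
        self._face_normals = None

    # -- unsigned -----------------------------------------------------------

    def query(self, points: np.ndarray):
        """Return (foot points, unsigned distances, face indices) for each
        query point.  Distances equal the exhaustive per-triangle minimum."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        n = len(points)
        m = self.mesh.n_faces
        if m <= 2 * self._k:
            return self._query_subset(points, np.tile(np.arange(m), (n, 1)))
        _, cand = self._tree.query(points, k=self._k, workers=-1)
        cand = np.atleast_2d(cand)
        foot0, dist0, face0 = self._query_subset(points, cand)
        # widen to every triangle whose centroid could still beat the bound
        radii = dist0 + self._rmax + 1e-12
        lists = self._tree.query_ball_point(points, radii, workers=-1)
        counts = np.fromiter((len(l) for l in lists), dtype=np.int64, count=n)
        flat = np.concatenate([np.asarray(l, dtype=np.int64) for l in lists])
        owner = np.repeat(np.arange(n), counts)
        p = points[owner]
        t = self._tri[flat]
        foot, d2 = _closest_on_triangles(p, t[:, 0], t[:, 1], t[:, 2])
        order = np.lexsort((d2, owner))
        starts = np.searchsorted(owner[order], np.arange(n))
        best = order[starts]
        return foot[best], np.sqrt(d2[best]), flat[best]

    def _query_subset(self, points, cand):
        n, k = cand.shape
        owner = np.repeat(np.arange(n), k)
        flat = cand.ravel()
        t = self._tri[flat]
        foot, d2 = _closest_on_triangles(points[owner], t[:, 0], t[:, 1], t[:, 2])
        d2m = d2.reshape(n, k)
        j = np.argmin(d2m, axis=1)
        rows = np.arange(n)
        idx = rows * k + j
        return foot[idx], np.sqrt(d2m[rows, j]), flat[idx]

    # -- signed -------------------------------------------------------------

    def _build_pseudonormals(self):
        mesh = self.mesh
        self._face_normals = mesh.face_normals()
        self._vertex_normals = mesh.vertex_normals()
        n = mesh.n_vertices
        f = mesh.faces
        e = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        keys = np.minimum(e[:, 0], e[:, 1]) * n + np.maximum(e[:, 0], e[:, 1])
        fn = np.tile(self._face_normals, (3, 1))
        uniq, inverse = np.unique(keys, return_inverse=True)
        acc = np.zeros((len(uniq), 3))
        np.add.at(acc, inverse, fn)
        norm = np.linalg.norm(acc, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        self._edge_keys = uniq
        self._edge_normals = acc / norm

    def signed(self, points: np.ndarray) -> np.ndarray:
        """Signed distances: positive on the outward-normal side."""
        _, sd, _ = self.query_signed(points)
        return sd

    def query_signed(self, points: np.ndarray):
        """Return (foot points, signed distances, face indices)."""
        if self._edge_normals is None:
            self._build_pseudonormals()
        points = np.atleast_2d(np.asarray(points, dtype=float))
        foot, dist, face = self.query(points)
        tri = self._tri[face]
        # barycentric coordinates of the foot point
        v0 = tri[:, 1] - tri[:, 0]
        v1 = tri[:, 2] - tri[:, 0]
        v2 = foot - tri[:, 0]
        d00 = np.einsum("ij,ij->i", v0, v0)
        d01 = np.einsum("ij,ij->i", v0, v1)
        d11 = np.einsum("ij,ij->i", v1, v1)
        d20 = np.einsum("ij,ij->i", v2, v0)
        d21 = np.einsum("ij,ij->i", v2, v1)
        denom = d00 * d11 - d01 * d01
        with np.errstate(divide="ignore", invalid="ignore"):
            bv = (d11 * d20 - d01 * d21) / denom
            bw = (d00 * d21 - d01 * d20) / denom
        bu = 1.0 - bv - bw
        bary = np.stack([bu, bv, bw], axis=1)
        eps = 1e-9
        on = bary > eps
        n_on = on.sum(axis=1)
        fverts = self.mesh.faces[face]
        normal = self._face_normals[face].copy()
        # vertex feet: angle-weighted normal of the dominant corner
        vmask = n_on <= 1
        if vmask.any():
            vi = fverts[vmask, np.argmax(bary[vmask], axis=1)]
            normal[vmask] = self._vertex_normals[vi]
        # edge feet: mean of the two adjacent face normals
        emask = n_on == 2
        if emask.any():
            nv = self.mesh.n_vertices
            pair = np.sort(
                np.stack(
                    [fverts[emask][on[emask]].reshape(-1, 2)[:, 0],
                     fverts[emask][on[emask]].reshape(-1, 2)[:, 1]],
                    axis=1,
                ),
                axis=1,
            )
            key = pair[:, 0] * nv + pair[:, 1]
            pos = np.searchsorted(self._edge_keys, key)
            normal[emask] = self._edge_normals[pos]
        signs = np.where(np.einsum("ij,ij->i", points - foot, normal) < 0, -1.0, 1.0)
        return foot, signs * dist, face


def closest_point(query: np.ndarray, mesh: TriangleMesh, index: ClosestPointIndex = None):
    """Closest surface point(s) to ``query``: (foot, unsigned mm, face id)."""
    index = index or ClosestPointIndex(mesh)
    q = np.asarray(query, dtype=float)
    single = q.ndim == 1
    foot, dist, face = index.query(q)
    if single:
        return foot[0], float(dist[0]), int(face[0])
    return foot, dist, face


def signed_distance(query: np.ndarray, mesh: TriangleMesh, index: ClosestPointIndex = None):
    """Signed point-to-surface distance(s): + = gap side, − = penetration."""
    index = index or ClosestPointIndex(mesh)
    q = np.asarray(query, dtype=float)
    out = index.signed(q)
    return float(out[0]) if q.ndim == 1 else out


# ---------------------------------------------------------------------------
# rigid alignment
# ---------------------------------------------------------------------------


def kabsch(source: np.ndarray, target: np.ndarray, weights: np.ndarray = None) -> RigidTransform:
    """Weighted least-squares rigid fit of ``source`` onto ``target``.

    Returns the proper rigid transform (no scaling, no reflection)
    minimising ``sum_i w_i ||R s_i + t - t_i||^2``.  Raises
    :class:`DegenerateGeometryError` for collinear configurations.
    """
    s = np.asarray(source, dtype=float).reshape(-1, 3)
    t = np.asarray(target, dtype=float).reshape(-1, 3)
    if s.shape != t.shape or len(s) < 3:
        raise ValueError("need matching source/target with k >= 3 points")
    if weights is None:
        w = np.full(len(s), 1.0 / len(s))
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w < 0) or w.sum() == 0:
            raise ValueError("weights must be nonnegative with positive sum")
        w = w / w.sum()
    mu_s = w @ s
    mu_t = w @ t
    H = (s - mu_s).T @ ((t - mu_t) * w[:, None])
    U, sing, Vt = np.linalg.svd(H)
    # collinearity: second singular value of the cross-covariance vanishes
    if sing[1] <= 1e-12 * max(sing[0], 1e-300):
        raise DegenerateGeometryError("points are collinear or coincident")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return RigidTransform(R, mu_t - R @ mu_s)


def apply_transform(obj, transform: RigidTransform):
    """Apply a rigid transform to an (n, 3) array or a mesh; returns a copy."""
    if isinstance(obj, TriangleMesh):
        out = obj.copy()
        out.vertices = transform.apply(out.vertices)
        return out
    return transform.apply(obj)


def mirror_sagittal(obj):
    """Reflect across the x = 0 sagittal plane.

    For meshes the face winding is flipped so outward orientation (and hence
    signed-distance signs) is preserved.
    """
    if isinstance(obj, TriangleMesh):
        out = obj.copy()
        out.vertices[:, 0] *= -1.0
        out.faces = out.faces[:, [0, 2, 1]]
        return out
    pts = np.array(obj, dtype=float, copy=True)
    pts[..., 0] *= -1.0
    return pts
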