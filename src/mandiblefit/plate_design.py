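"""Plate back-surface design from region quantile surfaces.

A plate is modelled by the geometry the fit analysis actually measures: the
sampled point set of its bone-facing back surface (with outward normals),
not a solid body.  The layout follows the two-miniplate osteosynthesis
principle — an upper bar in the tension zone near the alveolar border, a
lower bar in the pressure zone near the basal border, joined by evenly
spaced connectors — traced in the region's (a, b) parameter square and
evaluated on the S/M/L quantile surfaces of the region's shape model.

The design gives the plate three labelled start points (the two lower-bar
ends and the upper-bar midpoint) used for the three-point initial
positioning during virtual fitting.  Right-side plates are the sagittal
mirror of the left-side designs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .mesh import TriangleMesh, mirror_sagittal
from .shape_model import RegionShapeModel, DEFAULT_QUANTILES

__all__ = [
    "PlateLayout",
    "PlateGeometry",
    "DEFAULT_LAYOUTS",
    "trace_layout",
    "sample_plate",
    "design_plate_family",
    "mirror_plate",
    "plate_to_mesh",
]


@dataclass
class PlateLayout:
    """Bar/connector layout in the region's unit parameter square.

    ``a`` runs along the region's arch direction, ``b`` from the lower to
    the upper border.  All values are fractions in [0, 1].
    """

    a_start: float = 0.1
    a_end: float = 0.9
    v_low: float = 0.25
    v_high: float = 0.70
    n_connectors: int = 2
    keep_out_boxes: list = field(default_factory=list)  # [(a0, a1, b0, b1)]

    def __post_init__(self):
        if not (0 <= self.a_start < self.a_end <= 1):
            raise ValueError("need 0 <= a_start < a_end <= 1")
        if not (0 <= self.v_low < self.v_high <= 1):
            raise ValueError("bars overlap: need v_low < v_high")


#: per-type default layouts (artifact conventions; commercial extents are
#: proprietary)
DEFAULT_LAYOUTS = {
    "condyle": PlateLayout(0.10, 0.90, 0.25, 0.70, 2),
    "body": PlateLayout(0.10, 0.90, 0.22, 0.68, 3),
    "angle": PlateLayout(0.10, 0.90, 0.25, 0.72, 2),
    "symphysis": PlateLayout(0.15, 0.85, 0.20, 0.65, 3),
}

#: per-type available sizes (the symphysis plate exists in M and L only)
PLATE_SIZES = {
    "condyle": ("S", "M", "L"),
    "body": ("S", "M", "L"),
    "angle": ("S", "M", "L"),
    "symphysis": ("M", "L"),
}


@dataclass
class PlateGeometry:
    """Sampled back surface of one plate type/size.

    ``back_points``/``back_normals`` are the K sampled bone-facing points
    and unit outward normals; ``start_points`` are the three labelled
    initial-positioning points; ``start_uv`` are their (a, b) layout
    parameters so the matching ending points can be placed on any
    corresponded specimen.  ``index_map``/``grid_shape`` carry the source
    region's template topology for that purpose.
    """

    plate_type: str
    size: str
    side: str
    back_points: np.ndarray
    back_normals: np.ndarray
    start_points: np.ndarray  # (3, 3)
    start_uv: np.ndarray  # (3, 2)
    layout: PlateLayout
    index_map: np.ndarray
    grid_shape: tuple
    arc_length: float = 0.0

    def __post_init__(self):
        if len(self.back_points) < 30:
            raise ValueError(
                f"plate {self.plate_type}-{self.size}: only {len(self.back_points)} "
                "back points; need >= 30 (reduce sampling step)"
            )
        e1 = self.start_points[1] - self.start_points[0]
        e2 = self.start_points[2] - self.start_points[0]
        if np.linalg.norm(np.cross(e1, e2)) < 1e-9:
            raise ValueError("start points are collinear")

    @property
    def label(self) -> str:
        return f"{self.plate_type}-{self.size}-{self.side}"


def trace_layout(layout: PlateLayout) -> list:
    """Trace the layout into parametric curve segments in (a, b).

    Returns dicts ``{"kind", "start", "end"}``: the lower and upper bars
    plus ``n_connectors`` evenly spaced cross-links.
    """
    segs = [
        {"kind": "bar_lower", "start": (layout.a_start, layout.v_low),
         "end": (layout.a_end, layout.v_low)},
        {"kind": "bar_upper", "start": (layout.a_start, layout.v_high),
         "end": (layout.a_end, layout.v_high)},
    ]
    span = layout.a_end - layout.a_start
    for i in range(layout.n_connectors):
        a = layout.a_start + (i + 1) * span / (layout.n_connectors + 1)
        segs.append(
            {"kind": f"connector_{i}", "start": (a, layout.v_low), "end": (a, layout.v_high)}
        )
    return segs


def _in_keep_out(ab: np.ndarray, boxes) -> np.ndarray:
    hit = np.zeros(len(ab), dtype=bool)
    for a0, a1, b0, b1 in boxes:
        hit |= (ab[:, 0] >= a0) & (ab[:, 0] <= a1) & (ab[:, 1] >= b0) & (ab[:, 1] <= b1)
    return hit


class _GridSurface:
    """Bilinear evaluator over a region's (nu_r, nv) vertex grid."""

    def __init__(self, mesh: TriangleMesh, grid_shape):
        self.grid = mesh.vertices.reshape(*grid_shape, 3)
        vn = mesh.vertex_normals()
        self.normals = vn.reshape(*grid_shape, 3)
        self.shape = grid_shape

    def _bilinear(self, field_grid, ab):
        nu, nv = self.shape
        fa = np.clip(ab[:, 0], 0, 1) * (nu - 1)
        fb = np.clip(ab[:, 1], 0, 1) * (nv - 1)
        ia = np.minimum(fa.astype(int), nu - 2)
        ib = np.minimum(fb.astype(int), nv - 2)
        wa = (fa - ia)[:, None]
        wb = (fb - ib)[:, None]
        g = field_grid
        return (
            g[ia, ib] * (1 - wa) * (1 - wb)
            + g[ia + 1, ib] * wa * (1 - wb)
            + g[ia, ib + 1] * (1 - wa) * wb
            + g[ia + 1, ib + 1] * wa * wb
        )

    def points(self, ab):
        """Piecewise-linear evaluation on the *triangulated* surface (each
        quad is split along its v00-v11 diagonal), so sampled points lie
        exactly on the mesh."""
        nu, nv = self.shape
        ab = np.atleast_2d(ab)
        fa = np.clip(ab[:, 0], 0, 1) * (nu - 1)
        fb = np.clip(ab[:, 1], 0, 1) * (nv - 1)
        ia = np.minimum(fa.astype(int), nu - 2)
        ib = np.minimum(fb.astype(int), nv - 2)
        wa = (fa - ia)[:, None]
        wb = (fb - ib)[:, None]
        g = self.grid
        v00, v10 = g[ia, ib], g[ia + 1, ib]
        v01, v11 = g[ia, ib + 1], g[ia + 1, ib + 1]
        lower = v00 * (1 - wa) + v10 * (wa - wb) + v11 * wb
        upper = v00 * (1 - wb) + v01 * (wb - wa) + v11 * wa
        return np.where(wa >= wb, lower, upper)

    def unit_normals(self, ab):
        n = self._bilinear(self.normals, np.atleast_2d(ab))
        return n / np.linalg.norm(n, axis=1, keepdims=True)


def sample_plate(
    model: RegionShapeModel,
    size: str,
    layout: PlateLayout = None,
    sampling_step: float = 1.0,
    clearance: float = 0.0,
    quantiles: dict = None,
) -> PlateGeometry:
    """Sample a plate back surface from the region's quantile surface.

    ``sampling_step`` is the target spacing (mm) of back points along the
    layout curves; ``clearance`` offsets the back surface outward along the
    surface normal (0 = plate lies exactly on the design surface).
    """
    if model.grid_shape is None:
        raise ValueError("region model lacks grid structure; cannot trace a layout")
    layout = layout or DEFAULT_LAYOUTS[model.region.name]
    quantiles = quantiles or DEFAULT_QUANTILES
    if size not in quantiles:
        raise KeyError(f"unknown size {size!r}")
    surf_mesh = model.quantile_surface(quantiles[size])
    surf = _GridSurface(surf_mesh, model.grid_shape)

    segs = trace_layout(layout)
    pts, nrm, seg_ab = [], [], {}
    total_len = 0.0
    for seg in segs:
        a0 = np.asarray(seg["start"], dtype=float)
        a1 = np.asarray(seg["end"], dtype=float)
        coarse = surf.points(np.linspace(a0, a1, 12))
        seg_len = float(np.linalg.norm(np.diff(coarse, axis=0), axis=1).sum())
        total_len += seg_len
        n_samples = max(int(np.ceil(seg_len / sampling_step)) + 1, 4)
        ab = np.linspace(a0, a1, n_samples)
        if layout.keep_out_boxes:
            ab = ab[~_in_keep_out(ab, layout.keep_out_boxes)]
        if len(ab) == 0:
            raise ValueError(f"segment {seg['kind']} entirely inside keep-out boxes")
        seg_ab[seg["kind"]] = ab
        p = surf.points(ab)
        n = surf.unit_normals(ab)
        pts.append(p + clearance * n)
        nrm.append(n)

    lower = seg_ab["bar_lower"]
    upper = seg_ab["bar_upper"]
    start_uv = np.array([lower[0], lower[-1], upper[len(upper) // 2]])
    start_points = surf.points(start_uv) + clearance * surf.unit_normals(start_uv)
    return PlateGeometry(
        plate_type=model.region.name,
        size=size,
        side=model.region.side,
        back_points=np.concatenate(pts),
        back_normals=np.concatenate(nrm),
        start_points=start_points,
        start_uv=start_uv,
        layout=layout,
        index_map=model.index_map.copy(),
        grid_shape=model.grid_shape,
        arc_length=total_len,
    )


def design_plate_family(models: dict, sampling_step: float = 1.0, clearance: float = 0.0) -> list:
    """Design every type x size plate from a dict of region models
    (keys: condyle/body/angle/symphysis, left-side or midline models)."""
    plates = []
    for ptype, sizes in PLATE_SIZES.items():
        model = models[ptype]
        for size in sizes:
            plates.append(
                sample_plate(model, size, sampling_step=sampling_step, clearance=clearance)
            )
    return plates


def mirror_plate(plate: PlateGeometry) -> PlateGeometry:
    """Sagittal mirror (left <-> right) of a plate design."""
    side = {"left": "right", "right": "left"}.get(plate.side, plate.side)
    return replace(
        plate,
        side=side,
        back_points=mirror_sagittal(plate.back_points),
        back_normals=mirror_sagittal(plate.back_normals),
        start_points=mirror_sagittal(plate.start_points),
    )


def plate_to_mesh(plate: PlateGeometry, half_width: float = 1.0) -> TriangleMesh:
    """Thin ribbon triangulation of the back-point chain for visualisation
    / STL export.  Not used by the fit analysis."""
    p = plate.back_points
    n = plate.back_normals
    tang = np.gradient(p, axis=0)
    tang /= np.maximum(np.linalg.norm(tang, axis=1, keepdims=True), 1e-12)
    lateral = np.cross(n, tang)
    lateral /= np.maximum(np.linalg.norm(lateral, axis=1, keepdims=True), 1e-12)
    left = p - half_width * lateral
    right = p + half_width * lateral
    verts = np.concatenate([left, right])
    k = len(p)
    faces = []
    for i in range(k - 1):
        faces.append([i, k + i, k + i + 1])
        faces.append([i, k + i + 1, i + 1])
    return TriangleMesh(verts, np.array(faces, dtype=np.int64))


def plate_to_json(plate: PlateGeometry) -> dict:
    """Canonical JSON-serialisable form (points, normals, start points)."""
    return {
        "type": plate.plate_type,
        "size": plate.size,
        "side": plate.side,
        "back_points": plate.back_points.tolist(),
        "back_normals": plate.back_normals.tolist(),
        "start_points": plate.start_points.tolist(),
        "start_uv": plate.start_uv.tolist(),
        "arc_length_mm": plate.arc_length,
    }
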