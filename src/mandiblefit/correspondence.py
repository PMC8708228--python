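"""Template-to-target correspondence.

Raw surface meshes from different individuals share no vertex indexing.  To
build a statistical shape model every specimen must be re-expressed on the
template's topology so that vertex *k* marks the same anatomical location
throughout the sample ((pseudo)homology).  The full elastic registration
used on clinical data is a separate method; here a simpler, well-defined
stand-in is used that the synthetic cohort can validate exactly:

1. rigid landmark alignment (Kabsch over shared landmark names),
2. a 3D thin-plate-spline warp of the template onto the target landmarks
   (biharmonic kernel ``U(r) = r``),
3. closest-point projection of every warped template vertex onto the
   target surface.

The output has the template's topology with vertices on the target surface.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .mesh import (
    TriangleMesh,
    LandmarkSet,
    RigidTransform,
    ClosestPointIndex,
    DegenerateGeometryError,
    kabsch,
    apply_transform,
)
from .synthetic import CorrespondedCohort, Template

__all__ = [
    "align_landmarks",
    "ThinPlateSpline",
    "tps_warp",
    "project_correspondence",
    "register_cohort",
]

#: projections farther than this from the warped template are reported
DEFAULT_OUTLIER_RADIUS_MM = 5.0


def align_landmarks(template_lms: LandmarkSet, target_lms: LandmarkSet) -> RigidTransform:
    """Rigid (no-scaling) alignment of the template onto the target over
    the landmarks the two sets share by name."""
    shared = [n for n in template_lms.names if n in target_lms.names]
    if len(shared) < 3:
        raise ValueError(
            f"need >= 3 shared landmark names, got {len(shared)}: {shared}"
        )
    src = np.array([template_lms.get(n) for n in shared])
    dst = np.array([target_lms.get(n) for n in shared])
    return kabsch(src, dst)


class ThinPlateSpline(BaseEstimator, TransformerMixin):
    """3D thin-plate-spline interpolant with biharmonic kernel U(r) = r.

    Fits a smooth deformation carrying ``source`` control points exactly
    onto ``target`` control points (for ``regularization = 0``); affine
    control-point motions are reproduced exactly everywhere (zero bending
    energy).  Requires >= 4 non-coplanar control points.

    Parameters
    ----------
    regularization : float, default 0.0
        Ridge term lambda added to the kernel diagonal; positive values
        trade interpolation exactness for smoothness.
    """

    def __init__(self, regularization: float = 0.0):
        self.regularization = regularization

    def fit(self, X, y):
        """Fit the spline mapping control points ``X`` (k, 3) to ``y`` (k, 3)."""
        src = np.asarray(X, dtype=float).reshape(-1, 3)
        dst = np.asarray(y, dtype=float).reshape(-1, 3)
        if src.shape != dst.shape or len(src) < 4:
            raise ValueError("need >= 4 matching source/target control points")
        k = len(src)
        K = np.linalg.norm(src[:, None] - src[None, :], axis=2)
        K[np.diag_indices(k)] += self.regularization
        P = np.hstack([np.ones((k, 1)), src])
        A = np.zeros((k + 4, k + 4))
        A[:k, :k] = K
        A[:k, k:] = P
        A[k:, :k] = P.T
        b = np.zeros((k + 4, 3))
        b[:k] = dst
        try:
            sol = np.linalg.solve(A, b)
        except np.linalg.LinAlgError as exc:
            raise DegenerateGeometryError(
                "thin-plate-spline system is rank deficient (coplanar control points?)"
            ) from exc
        cond = np.linalg.cond(A)
        if not np.isfinite(cond) or cond > 1e13:
            raise DegenerateGeometryError(
                f"thin-plate-spline system is ill-conditioned (cond={cond:.2e}); "
                "control points are (near-)coplanar"
            )
        self.control_points_ = src
        self.weights_ = sol[:k]
        self.affine_ = sol[k:]
        return self

    def transform(self, X):
        """Evaluate the warp at points ``X`` (n, 3)."""
        pts = np.asarray(X, dtype=float).reshape(-1, 3)
        U = np.linalg.norm(pts[:, None] - self.control_points_[None], axis=2)
        P = np.hstack([np.ones((len(pts), 1)), pts])
        return U @ self.weights_ + P @ self.affine_


def tps_warp(template: TriangleMesh, source_lms: LandmarkSet, target_lms: LandmarkSet) -> TriangleMesh:
    """Warp the whole template mesh by the TPS interpolating the landmark
    pairs shared by name."""
    shared = [n for n in source_lms.names if n in target_lms.names]
    if len(shared) < 4:
        raise ValueError(f"need >= 4 shared landmarks for a 3D TPS, got {len(shared)}")
    src = np.array([source_lms.get(n) for n in shared])
    dst = np.array([target_lms.get(n) for n in shared])
    spline = ThinPlateSpline().fit(src, dst)
    out = template.copy()
    out.vertices = spline.transform(out.vertices)
    return out


def project_correspondence(
    warped_template: TriangleMesh,
    target: TriangleMesh,
    outlier_radius: float = DEFAULT_OUTLIER_RADIUS_MM,
):
    """Project every warped-template vertex to its closest point on the
    target surface.

    Returns ``(corresponded vertices, projection distances, outlier vertex
    indices)`` where outliers moved farther than ``outlier_radius`` mm (a
    warning is emitted when any exist)."""
    index = ClosestPointIndex(target)
    foot, dist, _ = index.query(warped_template.vertices)
    outliers = np.flatnonzero(dist > outlier_radius)
    if len(outliers):
        warnings.warn(
            f"{len(outliers)} projections exceed the {outlier_radius} mm outlier radius",
            stacklevel=2,
        )
    return foot, dist, outliers


def register_cohort(
    template: Template,
    targets: list,
    outlier_radius: float = DEFAULT_OUTLIER_RADIUS_MM,
):
    """Register raw target meshes to the template topology.

    Parameters
    ----------
    template : Template
        The annotated template (mesh + landmarks).
    targets : list of dict
        Each entry: ``{"id": str, "mesh": TriangleMesh,
        "landmarks": LandmarkSet or None, ...extra metadata columns}``.
        Specimens without usable landmarks are skipped with a warning.

    Returns
    -------
    (CorrespondedCohort, quality) where quality is a DataFrame with one row
    per processed specimen (id, rms_mm, max_mm, n_outliers).
    """
    verts, meta_rows, quality = [], [], []
    for entry in targets:
        sid = entry.get("id", f"target{len(verts)}")
        lms = entry.get("landmarks")
        if lms is None or len(set(lms.names) & set(template.landmarks.names)) < 4:
            warnings.warn(f"specimen {sid}: missing landmarks, skipped", stacklevel=2)
            continue
        rigid = align_landmarks(template.landmarks, lms)
        moved_lms = LandmarkSet(
            list(template.landmarks.names),
            rigid.apply(template.landmarks.points),
            list(template.landmarks.sides),
        )
        warped = tps_warp(apply_transform(template.mesh, rigid), moved_lms, lms)
        projected, dist, outliers = project_correspondence(
            warped, entry["mesh"], outlier_radius
        )
        verts.append(projected)
        meta_rows.append(
            {
                "id": sid,
                "sex": entry.get("sex", "?"),
                "group": entry.get("group", "?"),
                "age": entry.get("age", np.nan),
            }
        )
        quality.append(
            {
                "id": sid,
                "rms_mm": float(np.sqrt(np.mean(dist**2))),
                "max_mm": float(dist.max()),
                "n_outliers": int(len(outliers)),
            }
        )
    if not verts:
        raise ValueError("no specimen could be registered")
    cohort = CorrespondedCohort(
        template.mesh.faces.copy(), np.stack(verts), pd.DataFrame(meta_rows)
    )
    return cohort, pd.DataFrame(quality)
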