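"""Synthetic corresponded mandible-like cohorts with known ground truth.

Real mandible cohorts come from clinical CT segmentations that cannot be
redistributed, so the pipeline is exercised on a parametric stand-in: a
horseshoe ribbon surface (a semi-elliptical dental-arch centreline rising
posteriorly into two rami with condylar ends, swept from the lower border
``v = 0`` to the upper border ``v = 1``).  Anatomical realism is *not* the
goal — the generator only reproduces the statistical structure the analysis
assumes:

* a dominant size mode that is allometric (isotropic scaling combined with
  disproportionate ramus-height growth, so size and shape covary);
* secondary shape modes (arch width, gonial flare);
* group structure (sex, two population groups, bilateral symmetry);
* small per-vertex isotropic measurement noise.

Every specimen shares the template's vertex count and face topology, so the
cohort is corresponded by construction, and the true per-specimen mode
scores are retained for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mesh import TriangleMesh, LandmarkSet, RigidTransform, mirror_sagittal

__all__ = [
    "Template",
    "SyntheticCohortConfig",
    "GroundTruth",
    "CorrespondedCohort",
    "build_template",
    "sample_cohort",
    "perturb_rigid",
    "mode_fields",
    "training_cohort_config",
    "test_cohort_config",
    "REGION_U_INTERVALS",
]

# arch geometry (mm); |t| intervals defining the anatomical regions, where
# t = 2u - 1 runs from the left condyle (-1) through the symphysis (0) to
# the right condyle (+1)
_ARCH_HALF_WIDTH = 52.0
_ARCH_DEPTH = 55.0
_PHI_MAX = np.deg2rad(130.0)
_RAMUS_RISE = 35.0
_BODY_HEIGHT = 25.0
_RAMUS_EXTRA_HEIGHT = 18.0
_BULGE = 4.0

REGION_U_INTERVALS = {
    "symphysis": (0.0, 0.15),
    "body": (0.15, 0.5),
    "angle": (0.5, 0.78),
    "condyle": (0.78, 1.0),
}

#: keep-out landmark (mental foramen analogue) in (|t|, v) parameters
_FORAMEN_T = 0.30
_FORAMEN_V = 0.55
_FORAMEN_RADIUS_MM = 3.0


def _smoothstep(x):
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _ramus_ramp(t):
    """0 along the body, rising smoothly to 1 at the condyles."""
    return _smoothstep((np.abs(t) - 0.55) / 0.40)


def _surface_point(t, v):
    """Analytic template surface at arch parameter t in [-1, 1], height
    fraction v in [0, 1].  Vectorised over broadcastable t, v."""
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    phi = t * _PHI_MAX
    cx = _ARCH_HALF_WIDTH * np.sin(phi)
    cy = -_ARCH_DEPTH * np.cos(phi)
    ramp = _ramus_ramp(t)
    cz = _RAMUS_RISE * ramp
    height = _BODY_HEIGHT + _RAMUS_EXTRA_HEIGHT * ramp
    # outward horizontal normal of the elliptical centreline
    nx = _ARCH_DEPTH * np.sin(phi)
    ny = -_ARCH_HALF_WIDTH * np.cos(phi)
    nn = np.sqrt(nx**2 + ny**2)
    bulge = _BULGE * np.sin(np.pi * v)
    x = cx + bulge * nx / nn
    y = cy + bulge * ny / nn
    z = cz + v * height
    return np.stack(np.broadcast_arrays(x, y, z), axis=-1)


@dataclass
class Template:
    """The shared-topology template: mesh + parameterisation + annotations."""

    mesh: TriangleMesh
    landmarks: LandmarkSet
    regions: dict  # region name -> vertex index array
    keep_out: dict  # zone name -> {"vertex": index, "radius": mm}
    uv: np.ndarray  # (n_vertices, 2) grid parameters
    grid_shape: tuple  # (nu, nv)
    landmark_uv: np.ndarray = None  # (n_landmarks, 2) parameters of landmarks

    def grid_vertices(self, vertices: np.ndarray = None) -> np.ndarray:
        """Reshape a per-vertex array onto the (nu, nv, 3) grid."""
        v = self.mesh.vertices if vertices is None else vertices
        nu, nv = self.grid_shape
        return v.reshape(nu, nv, 3)


def build_template(resolution=(81, 10), shape_params=None) -> Template:
    """Build the parametric template surface with named regions, landmarks
    and keep-out zones.

    ``resolution = (nu, nv)`` gives a quad grid triangulated into
    ``2 (nu-1)(nv-1)`` faces; the surface is bilaterally symmetric about
    x = 0.  ``nu >= 20`` and ``nv >= 5`` are required for the regions and
    plate layouts to be resolvable.
    """
    nu, nv = resolution
    if nu < 20 or nv < 5:
        raise ValueError(f"template resolution too small: ({nu}, {nv}); need nu>=20, nv>=5")
    u = np.linspace(0.0, 1.0, nu)
    v = np.linspace(0.0, 1.0, nv)
    t = 2.0 * u - 1.0
    verts = _surface_point(t[:, None], v[None, :]).reshape(-1, 3)
    faces = []
    for iu in range(nu - 1):
        for iv in range(nv - 1):
            a = iu * nv + iv
            b = (iu + 1) * nv + iv
            faces.append([a, b, b + 1])
            faces.append([a, b + 1, a + 1])
    faces = np.asarray(faces, dtype=np.int64)
    mesh = TriangleMesh(verts, faces)
    # orient outward: the bulge normal at the mid-body must match the winding
    probe = nu // 4 * nv + nv // 2
    fn = mesh.face_normals()
    adj = np.any(faces == probe, axis=1)
    # outward = away from a point inside the arch at the probe's height
    centre = np.array([0.0, -_ARCH_DEPTH * 0.3, verts[probe][2]])
    out_dir = verts[probe] - centre
    if np.mean(fn[adj] @ out_dir) < 0:
        mesh.faces = mesh.faces[:, [0, 2, 1]]

    uv = np.stack(np.meshgrid(u, v, indexing="ij"), axis=-1).reshape(-1, 2)

    regions = {}
    tt = np.repeat(t, nv)
    for name, (lo, hi) in REGION_U_INTERVALS.items():
        if name == "symphysis":
            regions["symphysis"] = np.flatnonzero(np.abs(tt) <= hi)
        else:
            for side, sgn in (("left", -1), ("right", 1)):
                mask = (sgn * tt > lo) & (sgn * tt <= hi)
                regions[f"{name}-{side}"] = np.flatnonzero(mask)

    def nearest_vertex(t_q, v_q):
        iu = int(np.argmin(np.abs(t - t_q)))
        iv = int(np.argmin(np.abs(v - v_q)))
        return iu * nv + iv

    lm_spec = [
        ("gnathion", 0.0, 0.0, "midline"),
        ("infradentale", 0.0, 1.0, "midline"),
        ("gonion-left", -0.64, 0.15, "left"),
        ("gonion-right", 0.64, 0.15, "right"),
        ("condylion-left", -1.0, 1.0, "left"),
        ("condylion-right", 1.0, 1.0, "right"),
        ("foramen-left", -_FORAMEN_T, _FORAMEN_V, "left"),
        ("foramen-right", _FORAMEN_T, _FORAMEN_V, "right"),
    ]
    # landmark coordinates are evaluated on the discrete grid (not the
    # analytic surface) so specimen landmarks are exactly consistent
    lm_uv_arr = np.array([[(tq + 1.0) / 2.0, vq] for _, tq, vq, _ in lm_spec])
    lm_points = bilinear_grid_eval(verts.reshape(nu, nv, 3), lm_uv_arr)
    landmarks = LandmarkSet(
        [s[0] for s in lm_spec], lm_points, [s[3] for s in lm_spec]
    )
    keep_out = {
        "foramen-left": {
            "vertex": nearest_vertex(-_FORAMEN_T, _FORAMEN_V),
            "radius": _FORAMEN_RADIUS_MM,
        },
        "foramen-right": {
            "vertex": nearest_vertex(_FORAMEN_T, _FORAMEN_V),
            "radius": _FORAMEN_RADIUS_MM,
        },
    }
    mesh.vertex_labels = {k: np.asarray(ix) for k, ix in regions.items()}
    lm_uv = np.array([[(tq + 1.0) / 2.0, vq] for _, tq, vq, _ in lm_spec])
    return Template(mesh, landmarks, regions, keep_out, uv, (nu, nv), lm_uv)


# ---------------------------------------------------------------------------
# variation modes
# ---------------------------------------------------------------------------


def mode_fields(template: Template) -> np.ndarray:
    """The three analytic per-vertex displacement fields, shape (3, n, 3).

    Mode 1 — allometry: isotropic growth about the centroid *plus*
    disproportionate ramus-height growth (0.025 of shape per unit score plus
    0.35 mm·v per unit in the ramus ramp), so size and shape covary.
    Mode 2 — arch width: lateral scaling, 0.02·x mm per unit score.
    Mode 3 — gonial flare: outward bulge of the angle region, Gaussian in
    |t| around 0.64, 1 mm per unit score.
    """
    verts = template.mesh.vertices
    uv = template.uv
    t = 2.0 * uv[:, 0] - 1.0
    v = uv[:, 1]
    centroid = verts.mean(axis=0)

    f1 = 0.025 * (verts - centroid)
    f1[:, 2] += 0.35 * _ramus_ramp(t) * v

    f2 = np.zeros_like(verts)
    f2[:, 0] = 0.02 * verts[:, 0]

    phi = t * _PHI_MAX
    nx = _ARCH_DEPTH * np.sin(phi)
    ny = -_ARCH_HALF_WIDTH * np.cos(phi)
    nn = np.sqrt(nx**2 + ny**2)
    w = np.exp(-(((np.abs(t) - 0.64) / 0.12) ** 2))
    f3 = np.zeros_like(verts)
    f3[:, 0] = w * nx / nn
    f3[:, 1] = w * ny / nn

    return np.stack([f1, f2, f3])


# ---------------------------------------------------------------------------
# cohort sampling
# ---------------------------------------------------------------------------


@dataclass
class SyntheticCohortConfig:
    """Study-condition parameters of the synthetic population.

    ``demographics`` lists exact subgroup compositions as
    ``(sex, group, count)``; ``group_effects`` are additive mean shifts on
    the three mode scores per sex / group level (sexual dimorphism rides on
    the allometric mode by default).  ``seed`` reproduces the cohort exactly.
    """

    n_specimens: int = 127
    mode_sds: tuple = (2.0, 1.0, 0.5)
    group_effects: dict = field(
        default_factory=lambda: {
            "sex": {"M": (1.2, 0.0, 0.0), "F": (-1.2, 0.0, 0.0)},
            "group": {"European": (0.0, 0.4, 0.0), "Asian": (0.0, -0.4, 0.0)},
        }
    )
    demographics: list = None  # [(sex, group, count)]; None -> balanced
    age_means: dict = field(default_factory=lambda: {"European": 46.9, "Asian": 43.5})
    age_sds: dict = field(default_factory=lambda: {"European": 21.0, "Asian": 16.0})
    noise_sd: float = 0.05
    seed: int = 0
    template_resolution: tuple = (81, 10)

    def __post_init__(self):
        if self.n_specimens < 1:
            raise ValueError("n_specimens must be >= 1")
        if any(s < 0 for s in self.mode_sds) or self.noise_sd < 0:
            raise ValueError("standard deviations must be >= 0")


def training_cohort_config(**overrides) -> SyntheticCohortConfig:
    """The design-cohort composition: 127 specimens, 37 European
    (14 M / 23 F) and 90 Asian (48 M / 42 F)."""
    demo = [("M", "European", 14), ("F", "European", 23), ("M", "Asian", 48), ("F", "Asian", 42)]
    cfg = SyntheticCohortConfig(n_specimens=127, demographics=demo)
    for k, val in overrides.items():
        setattr(cfg, k, val)
    return cfg


def test_cohort_config(**overrides) -> SyntheticCohortConfig:
    """The fit-test cohort composition: 50 specimens, 30 European
    (18 M / 12 F) and 20 Asian (6 M / 14 F)."""
    demo = [("M", "European", 18), ("F", "European", 12), ("M", "Asian", 6), ("F", "Asian", 14)]
    cfg = SyntheticCohortConfig(n_specimens=50, demographics=demo, seed=1)
    for k, val in overrides.items():
        setattr(cfg, k, val)
    return cfg


@dataclass
class CorrespondedCohort:
    """Shared-topology mesh cohort: one face array, per-specimen vertices."""

    faces: np.ndarray
    vertices: np.ndarray  # (n_specimens, n_vertices, 3)
    metadata: pd.DataFrame  # columns: id, sex, group, age

    @property
    def n_specimens(self) -> int:
        return len(self.vertices)

    def specimen_mesh(self, k: int) -> TriangleMesh:
        return TriangleMesh(self.vertices[k].copy(), self.faces.copy())


@dataclass
class GroundTruth:
    """True per-specimen mode scores plus the generating template."""

    scores: np.ndarray  # (n_specimens, 3)
    metadata: pd.DataFrame
    template: Template


def _assign_demographics(config: SyntheticCohortConfig, rng: np.random.Generator):
    if config.demographics is not None:
        rows = []
        for sex, group, count in config.demographics:
            rows += [(sex, group)] * count
        if len(rows) != config.n_specimens:
            raise ValueError(
                f"demographics sum to {len(rows)} but n_specimens={config.n_specimens}"
            )
    else:
        sexes = np.where(rng.random(config.n_specimens) < 0.5, "M", "F")
        groups = np.where(rng.random(config.n_specimens) < 0.5, "European", "Asian")
        rows = list(zip(sexes, groups))
    ages = [
        float(np.clip(rng.normal(config.age_means[g], config.age_sds[g]), 18.0, 95.0))
        for _, g in rows
    ]
    return pd.DataFrame(
        {
            "id": [f"spec{i:03d}" for i in range(config.n_specimens)],
            "sex": [r[0] for r in rows],
            "group": [r[1] for r in rows],
            "age": ages,
        }
    )


def sample_cohort(config: SyntheticCohortConfig):
    """Draw a corresponded cohort from the template + mode model.

    Specimen k's vertices are
    ``template + sum_m score_km * field_m + noise`` with
    ``score_km ~ N(shift_m(sex_k, group_k), mode_sd_m^2)``.

    Returns ``(CorrespondedCohort, GroundTruth)``; byte-identical under the
    same seed.
    """
    rng = np.random.default_rng(config.seed)
    template = build_template(config.template_resolution)
    meta = _assign_demographics(config, rng)
    fields = mode_fields(template)
    n = config.n_specimens
    sds = np.asarray(config.mode_sds, dtype=float)
    scores = rng.normal(0.0, 1.0, size=(n, 3)) * sds
    for k in range(n):
        for factor, col in (("sex", "sex"), ("group", "group")):
            shifts = config.group_effects.get(factor, {})
            level = meta[col].iloc[k]
            if level in shifts:
                scores[k] += np.asarray(shifts[level], dtype=float)
    base = template.mesh.vertices
    verts = base[None] + np.einsum("km,mnd->knd", scores, fields)
    if config.noise_sd > 0:
        verts = verts + rng.normal(0.0, config.noise_sd, size=verts.shape)
    cohort = CorrespondedCohort(template.mesh.faces.copy(), verts, meta)
    return cohort, GroundTruth(scores, meta, template)


def perturb_rigid(mesh, rot_deg_max: float, trans_mm_max: float, seed: int):
    """Apply a random rigid motion of bounded magnitude; return the moved
    copy and the exact transform applied (for registration-recovery tests)."""
    if rot_deg_max < 0 or trans_mm_max < 0:
        raise ValueError("magnitudes must be >= 0")
    rng = np.random.default_rng(seed)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rot_deg_max) * rng.random()
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    tdir = rng.normal(size=3)
    tdir /= np.linalg.norm(tdir)
    tvec = trans_mm_max * rng.random() * tdir
    if rot_deg_max == 0:
        R = np.eye(3)
    if trans_mm_max == 0:
        tvec = np.zeros(3)
    transform = RigidTransform(R, tvec)
    if isinstance(mesh, TriangleMesh):
        out = mesh.copy()
        out.vertices = transform.apply(out.vertices)
    else:
        out = transform.apply(mesh)
    return out, transform


def bilinear_grid_eval(grid: np.ndarray, ab: np.ndarray) -> np.ndarray:
    """Bilinear interpolation of a (nu, nv, 3) vertex grid at (u, v) pairs."""
    nu, nv = grid.shape[:2]
    ab = np.atleast_2d(np.asarray(ab, dtype=float))
    fa = np.clip(ab[:, 0], 0, 1) * (nu - 1)
    fb = np.clip(ab[:, 1], 0, 1) * (nv - 1)
    ia = np.minimum(fa.astype(int), nu - 2)
    ib = np.minimum(fb.astype(int), nv - 2)
    wa = (fa - ia)[:, None]
    wb = (fb - ib)[:, None]
    return (
        grid[ia, ib] * (1 - wa) * (1 - wb)
        + grid[ia + 1, ib] * wa * (1 - wb)
        + grid[ia, ib + 1] * (1 - wa) * wb
        + grid[ia + 1, ib + 1] * wa * wb
    )


def specimen_landmarks(template: Template, vertices: np.ndarray) -> LandmarkSet:
    """The template landmarks carried onto one specimen's surface (bilinear
    evaluation of the specimen grid at the template landmark parameters)."""
    grid = vertices.reshape(*template.grid_shape, 3)
    pts = bilinear_grid_eval(grid, template.landmark_uv)
    return LandmarkSet(
        list(template.landmarks.names), pts, list(template.landmarks.sides)
    )


def save_cohort(cohort: CorrespondedCohort, ground_truth: GroundTruth, outdir) -> None:
    """Write one STL + landmark CSV per specimen plus ``cohort.csv`` and
    ``ground_truth.json`` (the on-disk cohort exchange format)."""
    import json
    from pathlib import Path

    from .mesh import write_stl, write_landmarks

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    template = ground_truth.template
    for k in range(cohort.n_specimens):
        sid = cohort.metadata["id"].iloc[k]
        write_stl(cohort.specimen_mesh(k), outdir / f"{sid}.stl")
        write_landmarks(
            specimen_landmarks(template, cohort.vertices[k]),
            outdir / f"{sid}_landmarks.csv",
        )
    cohort.metadata.to_csv(outdir / "cohort.csv", index=False)
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(
            {
                "scores": ground_truth.scores.tolist(),
                "ids": list(ground_truth.metadata["id"]),
            },
            fh,
        )
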