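"""Region statistical shape models: Procrustes alignment, PCA, allometry.

For each anatomical region the corresponded cohort is cropped to the
region's vertices, rigidly aligned by generalized Procrustes analysis
*without size standardisation* (so size stays in the data and the first
principal component carries allometric and sex-dimorphic variation),
factorised by PCA, and the region shape is regressed onto the PC1 score.
Design surfaces for plate sizes S/M/L are read off that regression at the
20/50/80% empirical quantiles of the PC1 scores; because the regression is
on an allometric component, the quantile surfaces do not scale isotropically
but carry the shape change associated with size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .mesh import TriangleMesh, RigidTransform, kabsch
from .synthetic import CorrespondedCohort, Template

__all__ = [
    "RegionDefinition",
    "GeneralizedProcrustesAlignment",
    "ShapeSpacePCA",
    "AllometricRegression",
    "RegionShapeModel",
    "extract_region",
    "gpa_rigid",
    "fit_pca",
    "regress_on_pc1",
    "quantile_surface",
    "DEFAULT_QUANTILES",
]

#: size -> PC1-score quantile used for the S/M/L design surfaces
DEFAULT_QUANTILES = {"S": 0.2, "M": 0.5, "L": 0.8}


@dataclass
class RegionDefinition:
    """A named anatomical region as a vertex-index set on the template."""

    name: str  # symphysis | body | angle | condyle
    side: str  # left | right | midline
    vertex_indices: np.ndarray

    def __post_init__(self):
        self.vertex_indices = np.asarray(self.vertex_indices, dtype=np.int64)
        if self.name == "symphysis" and self.side != "midline":
            raise ValueError("the symphysis region is midline")

    @classmethod
    def from_template(cls, template: Template, name: str, side: str = "midline"):
        key = name if side == "midline" else f"{name}-{side}"
        if key not in template.regions:
            raise KeyError(f"template has no region {key!r}")
        return cls(name, side, template.regions[key])


def extract_region(obj, region: RegionDefinition):
    """Crop a mesh or corresponded cohort to a region.

    Keeps faces whose three vertices all lie in the region and reindexes
    vertices densely.  Returns ``(cropped object, index_map)`` where
    ``index_map[i]`` is the template vertex index of cropped vertex ``i``.
    """
    idx = np.unique(region.vertex_indices)
    if idx.size == 0:
        raise ValueError(f"region {region.name} is empty")
    faces = obj.faces
    size = int(max(faces.max() if faces.size else 0, idx.max())) + 1
    lookup = -np.ones(size, dtype=np.int64)
    lookup[idx] = np.arange(len(idx))
    keep = np.all(lookup[faces] >= 0, axis=1)
    new_faces = lookup[faces[keep]]
    if isinstance(obj, CorrespondedCohort):
        out = CorrespondedCohort(new_faces, obj.vertices[:, idx], obj.metadata.copy())
    else:
        out = TriangleMesh(obj.vertices[idx].copy(), new_faces)
    return out, idx


# ---------------------------------------------------------------------------
# generalized Procrustes analysis (rigid, size preserved)
# ---------------------------------------------------------------------------


class GeneralizedProcrustesAlignment(BaseEstimator, TransformerMixin):
    """Iterative rigid alignment of a corresponded sample to its mean.

    No scaling is applied — centroid size stays in the data, which is what
    lets the subsequent PCA pick up allometry on its first component.

    Parameters
    ----------
    tol : float, mm
        Convergence threshold on the RMS displacement of the consensus mean
        between iterations.
    max_iter : int
        Hard iteration cap; exceeding it raises ``RuntimeError``.

    Attributes
    ----------
    mean_ : (p, 3) consensus mean, centred at the origin.
    aligned_ : (n, p, 3) aligned specimens.
    transforms_ : list of RigidTransform mapping raw input to aligned pose.
    n_iter_ : iterations used.
    objective_history_ : sum of squared residuals to the mean per iteration.
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 100):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X.reshape(len(X), -1, 3)
        n, p, _ = X.shape
        if n < 2:
            raise ValueError("GPA needs at least 2 specimens")
        centroids = X.mean(axis=1)
        centred = X - centroids[:, None, :]
        rotations = [np.eye(3) for _ in range(n)]
        aligned = centred.copy()
        mean = aligned.mean(axis=0)
        mean -= mean.mean(axis=0)
        history = []
        for it in range(self.max_iter):
            for k in range(n):
                tf = kabsch(centred[k], mean)
                rotations[k] = tf.rotation
                aligned[k] = centred[k] @ tf.rotation.T + tf.translation
            new_mean = aligned.mean(axis=0)
            new_mean -= new_mean.mean(axis=0)
            history.append(float(np.sum((aligned - new_mean[None]) ** 2)))
            shift = float(np.sqrt(np.mean((new_mean - mean) ** 2)))
            mean = new_mean
            if shift < self.tol:
                break
        else:
            raise RuntimeError(
                f"GPA did not converge in {self.max_iter} iterations "
                f"(last mean shift {shift:g} mm, objective {history[-1]:g})"
            )
        self.mean_ = mean
        self.aligned_ = aligned
        self.transforms_ = [
            RigidTransform(R, -R @ c) for R, c in zip(rotations, centroids)
        ]
        self.n_iter_ = it + 1
        self.objective_history_ = history
        return self

    def transform(self, X):
        """Align new specimens (n, p, 3) to the fitted consensus mean."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X.reshape(len(X), -1, 3)
        out = np.empty_like(X)
        for k, spec in enumerate(X):
            c = spec.mean(axis=0)
            tf = kabsch(spec - c, self.mean_)
            out[k] = (spec - c) @ tf.rotation.T + tf.translation
        return out


# ---------------------------------------------------------------------------
# PCA shape space
# ---------------------------------------------------------------------------


class ShapeSpacePCA(BaseEstimator, TransformerMixin):
    """PCA of aligned shapes via SVD of the centred data matrix.

    Attributes
    ----------
    mean_ : (3p,) mean shape (flattened).
    components_ : (r, 3p) orthonormal rows, descending variance.
    explained_variance_ : (r,) eigenvalues (ddof = n - 1).
    scores_ : (n, r) training-sample component coordinates (zero mean).
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 3:
            X = X.reshape(len(X), -1)
        n = len(X)
        if n < 2:
            raise ValueError("PCA needs at least 2 specimens")
        self.mean_ = X.mean(axis=0)
        centred = X - self.mean_
        U, s, Vt = np.linalg.svd(centred, full_matrices=False)
        r = max(1, int(np.sum(s > s[0] * 1e-12))) if s[0] > 0 else 1
        # deterministic sign: largest-magnitude loading positive
        for j in range(r):
            lead = np.argmax(np.abs(Vt[j]))
            if Vt[j, lead] < 0:
                Vt[j] = -Vt[j]
                U[:, j] = -U[:, j]
        self.components_ = Vt[:r]
        self.explained_variance_ = (s[:r] ** 2) / (n - 1)
        self.scores_ = centred @ self.components_.T
        self.n_specimens_ = n
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 3:
            X = X.reshape(len(X), -1)
        return (X - self.mean_) @ self.components_.T

    def inverse_transform(self, scores):
        scores = np.atleast_2d(np.asarray(scores, dtype=float))
        return self.mean_ + scores @ self.components_


# ---------------------------------------------------------------------------
# allometric regression of shape on the PC1 score
# ---------------------------------------------------------------------------


class AllometricRegression(BaseEstimator):
    """Per-coordinate ordinary least squares of shape on a single score.

    ``slope_[j] = Cov(x_j, s) / Var(s)``; ``intercept_`` is the predicted
    shape at score 0, equal to the sample mean shape when the scores are
    centred.  The empirical quantile function of the training scores
    (linear interpolation between order statistics) is retained so design
    surfaces can be indexed by population quantile.
    """

    def fit(self, scores, shapes):
        s = np.asarray(scores, dtype=float).ravel()
        X = np.asarray(shapes, dtype=float)
        if X.ndim == 3:
            X = X.reshape(len(X), -1)
        if len(s) != len(X):
            raise ValueError("scores and shapes disagree in length")
        var = s.var(ddof=0)
        if var <= 0:
            raise ValueError("zero variance in scores; regression undefined")
        sc = s - s.mean()
        self.slope_ = (sc @ (X - X.mean(axis=0))) / (sc @ sc)
        self.intercept_ = X.mean(axis=0) - self.slope_ * s.mean()
        self.scores_sorted_ = np.sort(s)
        return self

    def predict(self, score):
        score = np.asarray(score, dtype=float)
        return self.intercept_ + np.multiply.outer(score, self.slope_)

    def score_quantile(self, q: float) -> float:
        """Empirical quantile of the training scores (linear interpolation
        between order statistics)."""
        if not 0.0 < q < 1.0:
            raise ValueError(f"quantile must lie in (0, 1), got {q}")
        return float(np.quantile(self.scores_sorted_, q))


# ---------------------------------------------------------------------------
# assembled per-region model
# ---------------------------------------------------------------------------


@dataclass
class RegionShapeModel:
    """GPA + PCA + PC1 regression for one region, plus region topology."""

    region: RegionDefinition
    faces: np.ndarray
    index_map: np.ndarray  # cropped vertex -> template vertex index
    gpa: GeneralizedProcrustesAlignment
    pca: ShapeSpacePCA
    regression: AllometricRegression
    uv: np.ndarray = None  # (p, 2) template parameters of region vertices
    grid_shape: tuple = None  # (nu_region, nv) when grid-structured

    @classmethod
    def build(
        cls,
        cohort: CorrespondedCohort,
        region: RegionDefinition,
        template: Template = None,
        tol: float = 1e-8,
        max_iter: int = 100,
    ) -> "RegionShapeModel":
        sub, index_map = extract_region(cohort, region)
        gpa = GeneralizedProcrustesAlignment(tol=tol, max_iter=max_iter).fit(sub.vertices)
        pca = ShapeSpacePCA().fit(gpa.aligned_)
        # orient the allometric axis: PC1 score increases with centroid size,
        # so higher score quantiles give larger design surfaces
        csize = np.linalg.norm(
            gpa.aligned_.reshape(len(gpa.aligned_), -1), axis=1
        )
        if np.corrcoef(csize, pca.scores_[:, 0])[0, 1] < 0:
            pca.components_[0] *= -1.0
            pca.scores_[:, 0] *= -1.0
        reg = AllometricRegression().fit(pca.scores_[:, 0], gpa.aligned_)
        uv = grid_shape = None
        if template is not None:
            uv = template.uv[index_map]
            nv = template.grid_shape[1]
            iu = np.unique(index_map // nv)
            if len(index_map) == len(iu) * nv:
                grid_shape = (len(iu), nv)
        return cls(region, sub.faces, index_map, gpa, pca, reg, uv, grid_shape)

    @property
    def n_vertices(self) -> int:
        return len(self.index_map)

    def quantile_surface(self, q: float) -> TriangleMesh:
        """Design surface at population quantile ``q`` of the PC1 score."""
        return quantile_surface(self.pca, self.regression, q, self.faces)

    def size_surfaces(self, quantiles: dict = None) -> dict:
        """The S/M/L design surfaces (default 20/50/80% quantiles)."""
        quantiles = quantiles or DEFAULT_QUANTILES
        return {size: self.quantile_surface(q) for size, q in quantiles.items()}

    # -- serialization ------------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "region": {"name": self.region.name, "side": self.region.side,
                       "vertex_indices": self.region.vertex_indices.tolist()},
            "faces": self.faces.tolist(),
            "index_map": self.index_map.tolist(),
            "mean": self.pca.mean_.tolist(),
            "components": self.pca.components_.tolist(),
            "explained_variance": self.pca.explained_variance_.tolist(),
            "scores": self.pca.scores_.tolist(),
            "slope": self.regression.slope_.tolist(),
            "intercept": self.regression.intercept_.tolist(),
            "scores_sorted": self.regression.scores_sorted_.tolist(),
            "uv": None if self.uv is None else self.uv.tolist(),
            "grid_shape": self.grid_shape,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "RegionShapeModel":
        with open(path) as fh:
            d = json.load(fh)
        region = RegionDefinition(
            d["region"]["name"], d["region"]["side"], np.array(d["region"]["vertex_indices"])
        )
        pca = ShapeSpacePCA()
        pca.mean_ = np.array(d["mean"])
        pca.components_ = np.array(d["components"])
        pca.explained_variance_ = np.array(d["explained_variance"])
        pca.scores_ = np.array(d["scores"])
        pca.n_specimens_ = len(pca.scores_)
        reg = AllometricRegression()
        reg.slope_ = np.array(d["slope"])
        reg.intercept_ = np.array(d["intercept"])
        reg.scores_sorted_ = np.array(d["scores_sorted"])
        return cls(
            region,
            np.array(d["faces"], dtype=np.int64),
            np.array(d["index_map"], dtype=np.int64),
            GeneralizedProcrustesAlignment(),
            pca,
            reg,
            None if d["uv"] is None else np.array(d["uv"]),
            None if d["grid_shape"] is None else tuple(d["grid_shape"]),
        )


# ---------------------------------------------------------------------------
# thin functional wrappers
# ---------------------------------------------------------------------------


def gpa_rigid(vertices, tol: float = 1e-8, max_iter: int = 100):
    """Rigid GPA of an (n, p, 3) sample; returns (aligned, mean, transforms)."""
    est = GeneralizedProcrustesAlignment(tol=tol, max_iter=max_iter).fit(vertices)
    return est.aligned_, est.mean_, est.transforms_


def fit_pca(aligned) -> ShapeSpacePCA:
    """PCA of aligned shapes (n, p, 3) or (n, 3p)."""
    return ShapeSpacePCA().fit(aligned)


def regress_on_pc1(aligned, scores) -> AllometricRegression:
    """OLS of shape on the PC1 score."""
    return AllometricRegression().fit(scores, aligned)


def quantile_surface(
    pca: ShapeSpacePCA, regression: AllometricRegression, q: float, faces
) -> TriangleMesh:
    """Surface predicted at the empirical quantile ``q`` of PC1 scores."""
    s_q = regression.score_quantile(q)
    verts = regression.predict(s_q).reshape(-1, 3)
    return TriangleMesh(verts, np.asarray(faces, dtype=np.int64))
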