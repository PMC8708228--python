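"""Statistical shape model tests: region extraction, GPA, PCA, allometric
regression and quantile surfaces."""

import numpy as np
import pytest

from mandiblefit.mesh import kabsch
from mandiblefit.synthetic import (
    SyntheticCohortConfig,
    sample_cohort,
    perturb_rigid,
    training_cohort_config,
)
from mandiblefit.shape_model import (
    RegionDefinition,
    RegionShapeModel,
    GeneralizedProcrustesAlignment,
    ShapeSpacePCA,
    AllometricRegression,
    extract_region,
    gpa_rigid,
    fit_pca,
    regress_on_pc1,
    quantile_surface,
    DEFAULT_QUANTILES,
)


# ---------------------------------------------------------------------------
# region extraction
# ---------------------------------------------------------------------------


class TestExtractRegion:
    def test_full_region_is_identity(self, template):
        region = RegionDefinition("body", "left", np.arange(template.mesh.n_vertices))
        sub, index_map = extract_region(template.mesh, region)
        np.testing.assert_array_equal(sub.vertices, template.mesh.vertices)
        assert sub.n_faces == template.mesh.n_faces

    def test_single_triangle_region(self, template):
        face = template.mesh.faces[0]
        sub, _ = extract_region(template.mesh, RegionDefinition("body", "left", face))
        assert sub.n_faces == 1
        assert sub.n_vertices == 3

    def test_face_count_matches_bruteforce(self, template):
        region = RegionDefinition.from_template(template, "angle", "left")
        sub, _ = extract_region(template.mesh, region)
        in_region = np.zeros(template.mesh.n_vertices, dtype=bool)
        in_region[region.vertex_indices] = True
        expected = sum(1 for f in template.mesh.faces if in_region[f].all())
        assert sub.n_faces == expected

    def test_empty_region_error(self, template):
        with pytest.raises(ValueError, match="empty"):
            extract_region(template.mesh, RegionDefinition("body", "left", np.array([], int)))


# ---------------------------------------------------------------------------
# GPA
# ---------------------------------------------------------------------------


def _rigid_copies(shape, n, seed=0):
    return np.stack([perturb_rigid(shape, 30.0, 20.0, seed=seed + k)[0] for k in range(n)])


class TestGPA:
    def test_rigid_motions_collapse_to_zero_residual(self):
        rng = np.random.default_rng(0)
        shape = rng.normal(scale=10.0, size=(30, 3))
        cohort = _rigid_copies(shape, 5)
        aligned, mean, _ = gpa_rigid(cohort)
        assert np.max(np.abs(aligned - mean[None])) < 1e-6
        # mean is the input shape up to a rigid motion: residual of the
        # rigid fit is zero
        tf = kabsch(shape - shape.mean(axis=0), mean)
        np.testing.assert_allclose(tf.apply(shape - shape.mean(axis=0)), mean, atol=1e-6)

    def test_identical_pair(self):
        shape = np.random.default_rng(1).normal(size=(10, 3))
        aligned, mean, _ = gpa_rigid(np.stack([shape, shape]))
        np.testing.assert_allclose(aligned[0], aligned[1], atol=1e-12)

    def test_objective_nonincreasing(self, cohort_and_truth):
        cohort, truth = cohort_and_truth
        region = RegionDefinition.from_template(truth.template, "body", "left")
        sub, _ = extract_region(cohort, region)
        est = GeneralizedProcrustesAlignment().fit(sub.vertices)
        h = est.objective_history_
        assert all(h[i + 1] <= h[i] + 1e-9 for i in range(len(h) - 1))

    def test_invariant_to_rigid_pretransform(self, cohort_and_truth):
        """Rigidly moving one input specimen does not change the aligned
        ensemble (up to the global output rotation, which is a convention)."""
        cohort, truth = cohort_and_truth
        region = RegionDefinition.from_template(truth.template, "condyle", "left")
        sub, _ = extract_region(cohort, region)
        X = sub.vertices[:10]
        a1 = GeneralizedProcrustesAlignment().fit(X)
        X2 = X.copy()
        X2[3] = perturb_rigid(X2[3], 25.0, 15.0, seed=9)[0]
        a2 = GeneralizedProcrustesAlignment().fit(X2)
        # remove the global rotation freedom by aligning the two means
        tf = kabsch(a2.mean_, a1.mean_)
        realigned = np.stack([tf.apply(s) for s in a2.aligned_])
        np.testing.assert_allclose(realigned, a1.aligned_, atol=1e-6)

    def test_no_scaling_size_preserved(self):
        """Centroid size of every specimen is unchanged by the alignment."""
        rng = np.random.default_rng(5)
        # mutually unrelated shapes: the consensus is weak, so allow the
        # alternating optimisation more iterations than the default
        X = rng.normal(scale=10.0, size=(6, 20, 3)) * np.array([3.0, 1.0, 0.3])
        est = GeneralizedProcrustesAlignment(max_iter=1000).fit(X)
        before = [np.linalg.norm(x - x.mean(axis=0)) for x in X]
        after = [np.linalg.norm(a - a.mean(axis=0)) for a in est.aligned_]
        np.testing.assert_allclose(before, after, rtol=1e-12)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


class TestPCA:
    def test_rank_one_data_single_eigenvalue(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=30)
        direction = rng.normal(size=30)
        X = base + np.linspace(-2, 2, 7)[:, None] * direction
        pca = ShapeSpacePCA().fit(X)
        assert len(pca.explained_variance_) == 1

    def test_eigenvalue_sum_equals_total_variance(self, cohort_and_truth):
        cohort, _ = cohort_and_truth
        X = cohort.vertices[:20].reshape(20, -1)
        pca = ShapeSpacePCA().fit(X)
        total = np.sum((X - X.mean(axis=0)) ** 2) / (20 - 1)
        assert pca.explained_variance_.sum() == pytest.approx(total, rel=1e-9)

    def test_matches_dense_covariance_eigensolve(self):
        """5-specimen toy cohort: SVD route equals the brute-force
        eigendecomposition of the dense covariance matrix."""
        rng = np.random.default_rng(7)
        X = rng.normal(size=(5, 12))
        pca = ShapeSpacePCA().fit(X)
        C = np.cov(X, rowvar=False, ddof=1)
        evals, evecs = np.linalg.eigh(C)
        evals, evecs = evals[::-1], evecs[:, ::-1]
        r = len(pca.explained_variance_)
        np.testing.assert_allclose(pca.explained_variance_, evals[:r], atol=1e-8)
        for j in range(r):  # eigenvectors defined up to sign
            dot = abs(np.dot(pca.components_[j], evecs[:, j]))
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_invariants(self, cohort_and_truth):
        cohort, _ = cohort_and_truth
        pca = ShapeSpacePCA().fit(cohort.vertices[:15])
        G = pca.components_ @ pca.components_.T
        np.testing.assert_allclose(G, np.eye(len(G)), atol=1e-9)
        assert np.all(np.diff(pca.explained_variance_) <= 1e-12)
        np.testing.assert_allclose(pca.scores_.mean(axis=0), 0, atol=1e-9)

    def test_full_reconstruction(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(8, 21))
        pca = ShapeSpacePCA().fit(X)
        back = pca.inverse_transform(pca.transform(X))
        np.testing.assert_allclose(back, X, atol=1e-10)


# ---------------------------------------------------------------------------
# allometric regression + quantile surfaces
# ---------------------------------------------------------------------------


class TestAllometricRegression:
    def test_slope_equals_first_component(self, cohort_and_truth):
        """Regressing aligned shapes on their own exact PC1 scores returns
        the first component as slope (closed-form identity)."""
        cohort, truth = cohort_and_truth
        region = RegionDefinition.from_template(truth.template, "body", "left")
        sub, _ = extract_region(cohort, region)
        aligned, _, _ = gpa_rigid(sub.vertices)
        pca = fit_pca(aligned)
        reg = regress_on_pc1(aligned, pca.scores_[:, 0])
        np.testing.assert_allclose(reg.slope_, pca.components_[0], atol=1e-9)

    def test_prediction_at_mean_score_is_mean_shape(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 9))
        s = rng.normal(size=20)
        reg = AllometricRegression().fit(s, X)
        np.testing.assert_allclose(reg.predict(s.mean()), X.mean(axis=0), atol=1e-10)

    def test_rank_one_zero_residual(self):
        s = np.linspace(-1, 1, 9)
        direction = np.arange(6.0)
        X = 3.0 + np.outer(s, direction)
        reg = AllometricRegression().fit(s, X)
        np.testing.assert_allclose(reg.predict(s), X, atol=1e-10)

    def test_zero_score_variance_error(self):
        with pytest.raises(ValueError, match="variance"):
            AllometricRegression().fit(np.ones(5), np.random.default_rng(0).normal(size=(5, 6)))


class TestQuantileSurface:
    def test_invalid_quantile(self, region_models):
        with pytest.raises(ValueError):
            region_models["body"].quantile_surface(0.0)
        with pytest.raises(ValueError):
            region_models["body"].quantile_surface(1.2)

    def test_symmetric_scores_median_is_mean(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 9))
        s = np.concatenate([np.linspace(-2, 2, 10)])  # symmetric scores
        reg = AllometricRegression().fit(s, X)
        pca = ShapeSpacePCA().fit(X)
        surf = quantile_surface(pca, reg, 0.5, np.array([[0, 1, 2]]))
        np.testing.assert_allclose(
            surf.vertices.ravel(), reg.predict(0.0), atol=1e-9
        )

    def test_centroid_size_increases_with_quantile(self, region_models):
        """With an allometric dominant mode, the S/M/L quantile surfaces
        grow strictly in centroid size."""
        for ptype, model in region_models.items():
            sizes = []
            for q in (0.2, 0.5, 0.8):
                v = model.quantile_surface(q).vertices
                sizes.append(np.linalg.norm(v - v.mean(axis=0)))
            assert sizes[0] < sizes[1] < sizes[2], ptype

    def test_straight_path_in_shape_space(self, region_models):
        """surface(q) moves along a fixed direction: the q=0.5 surface lies
        on the segment between q=0.2 and q=0.8 surfaces."""
        model = region_models["angle"]
        v = {q: model.quantile_surface(q).vertices.ravel() for q in (0.2, 0.5, 0.8)}
        d1 = v[0.5] - v[0.2]
        d2 = v[0.8] - v[0.2]
        # collinearity: residual of projecting d1 on d2 is ~0
        resid = d1 - (d1 @ d2) / (d2 @ d2) * d2
        assert np.linalg.norm(resid) < 1e-9 * np.linalg.norm(d2)


class TestParameterRecovery:
    def test_pc1_recovers_true_allometric_scores(self):
        """Study-scale recovery: n=127, dominant allometric mode,
        noise 0.05 mm -> |corr(PC1 scores, true mode-1 scores)| > 0.95."""
        cfg = training_cohort_config(seed=21, noise_sd=0.05)
        cohort, truth = sample_cohort(cfg)
        region = RegionDefinition.from_template(truth.template, "body", "left")
        model = RegionShapeModel.build(cohort, region, truth.template)
        r = np.corrcoef(model.pca.scores_[:, 0], truth.scores[:, 0])[0, 1]
        assert abs(r) > 0.95

    def test_serialization_roundtrip(self, region_models, tmp_path):
        model = region_models["condyle"]
        path = tmp_path / "m.json"
        model.to_json(path)
        back = RegionShapeModel.from_json(path)
        np.testing.assert_allclose(
            back.quantile_surface(0.5).vertices,
            model.quantile_surface(0.5).vertices,
            atol=1e-12,
        )
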