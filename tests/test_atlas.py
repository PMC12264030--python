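"""Generalised Procrustes alignment and PCA atlas construction."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import lvatlas as lv
from lvatlas.atlas import generalised_procrustes, kabsch_rotation, rigid_align
from lvatlas.errors import DimensionError, InvalidParameterError

from conftest import rigid_motion


def centroid_size(shape):
    pts = shape.reshape(-1, 3)
    return np.linalg.norm(pts - pts.mean(axis=0))


class TestGPA:
    def test_rigid_pair_collapses_to_one_shape(self, base_shape):
        moved = rigid_motion(base_shape, seed=1)
        aligned, mean, _ = generalised_procrustes(np.stack([base_shape, moved]))
        np.testing.assert_allclose(aligned[0], aligned[1], atol=1e-8)
        np.testing.assert_allclose(aligned[0], mean, atol=1e-8)

    def test_repeated_shape_identical_up_to_common_frame(self, base_shape):
        stack = np.stack([base_shape] * 5)
        aligned, mean, _ = generalised_procrustes(stack)
        for row in aligned:
            np.testing.assert_allclose(row, mean, atol=1e-8)
        # common frame is rigidly related to the input
        assert centroid_size(mean) == pytest.approx(centroid_size(base_shape), rel=1e-12)

    def test_scaling_kept_intact(self, base_shape):
        small = base_shape
        big = rigid_motion(2.0 * base_shape, seed=2)
        aligned, _, _ = generalised_procrustes(np.stack([small, big]))
        ratio = centroid_size(aligned[1]) / centroid_size(aligned[0])
        assert ratio == pytest.approx(2.0, rel=1e-12)

    def test_centroid_size_preserved_exactly(self, small_cohort):
        _, shapes, _ = small_cohort
        aligned, _, _ = generalised_procrustes(shapes[:20])
        before = [centroid_size(s) for s in shapes[:20]]
        after = [centroid_size(s) for s in aligned]
        np.testing.assert_allclose(after, before, rtol=1e-12)

    def test_idempotence(self, small_cohort):
        _, shapes, _ = small_cohort
        aligned, mean, _ = generalised_procrustes(shapes[:15])
        again, mean2, _ = generalised_procrustes(aligned)
        np.testing.assert_allclose(again, aligned, atol=1e-5)
        np.testing.assert_allclose(mean2, mean, atol=1e-5)

    def test_non_homologous_raises(self):
        with pytest.raises(DimensionError):
            rigid_align(np.zeros(12), np.zeros(9))

    def test_fewer_than_two_shapes_raises(self):
        with pytest.raises(InvalidParameterError):
            generalised_procrustes(np.zeros((1, 12)))


def test_kabsch_matches_scipy_brute_force():
    """Pairwise optimal rotations agree with the reference solver at tiny n."""
    rng = np.random.default_rng(0)
    for _ in range(10):
        n_pts = rng.integers(4, 13)
        a = rng.standard_normal((n_pts, 3))
        b = rng.standard_normal((n_pts, 3))
        a -= a.mean(0)
        b -= b.mean(0)
        r_own = kabsch_rotation(a, b)
        r_ref, _ = Rotation.align_vectors(b, a)  # maps a onto b
        np.testing.assert_allclose(r_own, r_ref.as_matrix(), atol=1e-8)
        assert np.linalg.det(r_own) == pytest.approx(1.0, abs=1e-10)


class TestAtlasPCA:
    def _aligned_mode_shapes(self, n, sds, seed=0, dim_pts=40):
        """Shapes = base + sum t_k d_k with modes orthogonal to the rigid
        tangent space, so GPA leaves the variation intact."""
        rng = np.random.default_rng(seed)
        base = rng.standard_normal((dim_pts, 3)) * 10.0
        c = base - base.mean(0)
        tangent = []
        for ax in range(3):  # translations
            t = np.zeros((dim_pts, 3))
            t[:, ax] = 1.0
            tangent.append(t.ravel())
        for ax in np.eye(3):  # infinitesimal rotations
            tangent.append(np.cross(c, ax).ravel())
        tangent = np.stack(tangent)
        q_t, _ = np.linalg.qr(tangent.T)
        modes = rng.standard_normal((3 * dim_pts, len(sds)))
        modes -= q_t @ (q_t.T @ modes)
        modes, _ = np.linalg.qr(modes)
        coefs = rng.standard_normal((n, len(sds))) * np.asarray(sds)
        shapes = base.ravel() + coefs @ modes.T
        return shapes, modes.T

    def test_rank_one_recovery(self):
        shapes, modes = self._aligned_mode_shapes(50, [2.0])
        atlas = lv.ShapeAtlas().fit(shapes)
        assert atlas.n_components_ == 1
        assert abs(atlas.components_[0] @ modes[0]) == pytest.approx(1.0, abs=1e-6)
        assert atlas.variance_fraction_retained_ == pytest.approx(1.0, abs=1e-9)

    def test_known_modes_recovered(self):
        shapes, modes = self._aligned_mode_shapes(500, [3.0, 2.0, 1.0], seed=4)
        atlas = lv.ShapeAtlas().fit(shapes)
        assert atlas.n_components_ >= 3
        for k, var in enumerate([9.0, 4.0, 1.0]):
            assert atlas.explained_variance_[k] == pytest.approx(var, rel=0.15)
            cos = abs(atlas.components_[k] @ modes[k])
            assert cos > 0.95

    def test_full_cutoff_reconstructs_training_shapes(self, small_cohort):
        _, shapes, _ = small_cohort
        atlas = lv.ShapeAtlas(variance_cutoff=1.0).fit(shapes[:25])
        recon = atlas.inverse_transform(atlas.training_scores_)
        aligned, _, _ = generalised_procrustes(shapes[:25])
        err = np.linalg.norm(recon - aligned) / np.linalg.norm(aligned)
        assert err < 1e-6

    def test_components_orthonormal_and_variances_sorted(self, fitted_atlas):
        g = fitted_atlas.components_ @ fitted_atlas.components_.T
        np.testing.assert_allclose(g, np.eye(fitted_atlas.n_components_), atol=1e-8)
        v = fitted_atlas.explained_variance_
        assert np.all(np.diff(v) <= 1e-12)
        assert fitted_atlas.variance_fraction_retained_ >= 0.999


class TestProjection:
    def test_mean_shape_projects_to_zero(self, fitted_atlas):
        scores = fitted_atlas.transform(fitted_atlas.mean_shape_[None])
        np.testing.assert_allclose(scores, 0.0, atol=1e-8)

    def test_training_shapes_reproduce_training_scores(self, small_cohort, fitted_atlas):
        _, shapes, _ = small_cohort
        scores = fitted_atlas.transform(shapes)
        np.testing.assert_allclose(scores, fitted_atlas.training_scores_, atol=1e-8)

    def test_rigidly_moved_copy_same_scores(self, small_cohort, fitted_atlas):
        _, shapes, _ = small_cohort
        moved = rigid_motion(shapes[3], seed=9)
        s1 = fitted_atlas.transform(shapes[3][None])
        s2 = fitted_atlas.transform(moved[None])
        np.testing.assert_allclose(s1, s2, atol=1e-6)

    def test_dimension_mismatch_raises(self, fitted_atlas):
        with pytest.raises(DimensionError):
            fitted_atlas.transform(np.zeros((1, 99)))


class TestReconstruct:
    def test_zero_scores_give_mean(self, fitted_atlas):
        np.testing.assert_allclose(
            fitted_atlas.inverse_transform(np.zeros(fitted_atlas.n_components_)),
            fitted_atlas.mean_shape_,
        )

    def test_unit_score_displacement_norm(self, fitted_atlas):
        s = np.zeros(fitted_atlas.n_components_)
        s[0] = 1.0
        shape = fitted_atlas.inverse_transform(s)
        assert np.linalg.norm(shape - fitted_atlas.mean_shape_) == pytest.approx(1.0, abs=1e-9)

    def test_project_reconstruct_within_residual(self, small_cohort, fitted_atlas):
        _, shapes, _ = small_cohort
        scores = fitted_atlas.transform(shapes[:5])
        recon = fitted_atlas.inverse_transform(scores)
        residual = fitted_atlas.last_projection_residual_[:5]
        aligned = np.stack(
            [rigid_align(s, fitted_atlas.mean_shape_) for s in shapes[:5]]
        )
        np.testing.assert_allclose(
            np.linalg.norm(recon - aligned, axis=1), residual, atol=1e-8
        )


def test_persistence_round_trip(tmp_path, small_cohort, fitted_atlas):
    _, shapes, _ = small_cohort
    fitted_atlas.save(tmp_path / "atlas")
    loaded = lv.ShapeAtlas.load(tmp_path / "atlas")
    np.testing.assert_allclose(
        loaded.transform(shapes[:4]), fitted_atlas.transform(shapes[:4]), atol=1e-10
    )
    assert loaded.n_components_ == fitted_atlas.n_components_


def test_dimensionality_reduction_arithmetic():
    assert round(lv.dimensionality_reduction_percent(176, 9420), 1) == 98.1
    assert round(lv.dimensionality_reduction_percent(210, 9420), 1) == 97.8
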