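import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msheadem.experiments import bspline_eval_brute
from msheadem.registration import bspline_weights
from msheadem.registration import (FFDGrid, NonRigidICP, SimilarityTransform,
                                   ffd_displacement, ffd_transform,
                                   fit_ffd_scattered, fit_similarity_landmarks,
                                   refine_ffd, subdivide_ffd)


def random_grid(rng, spacing=5.0, box=20.0, zero_border=False):
    g = FFDGrid.covering((0, 0, 0), (box, box, box), spacing)
    d = rng.normal(0, 1, g.disp.shape)
    if zero_border:
        d[:2] = d[-2:] = 0
        d[:, :2] = d[:, -2:] = 0
        d[:, :, :2] = d[:, :, -2:] = 0
    g.disp = d
    return g


class TestSimilarity:
    def test_identity(self):
        pts = np.array([[0.0, 0, 0], [10, 0, 0], [0, 10, 0]])
        s = fit_similarity_landmarks(pts, pts)
        assert np.allclose(s.matrix, np.eye(4), atol=1e-12)

    def test_construct_and_recover(self):
        pts = np.array([[1.0, 2, 3], [-4, 5, 0], [2, -7, 4]])
        th = np.deg2rad(30)
        R = np.array([[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0],
                      [0, 0, 1.0]])
        true = SimilarityTransform(R, 1.1, (5.0, -2.0, 1.0))
        fit = fit_similarity_landmarks(pts, true.apply(pts))
        assert np.abs(fit.matrix - true.matrix).max() < 1e-9

    def test_centroids_aligned(self, rng):
        src = rng.uniform(-10, 10, (3, 3))
        dst = rng.uniform(-10, 10, (3, 3))
        fit = fit_similarity_landmarks(src, dst)
        assert np.linalg.norm(fit.apply(src).mean(0) - dst.mean(0)) < 1e-9

    def test_collinear_rejected(self):
        pts = np.array([[0.0, 0, 0], [1, 1, 1], [2, 2, 2]])
        with pytest.raises(ValueError, match="collinear"):
            fit_similarity_landmarks(pts, pts + 1.0)

    def test_inverse_roundtrip(self, rng):
        src = rng.uniform(-10, 10, (3, 3))
        dst = rng.uniform(-10, 10, (3, 3))
        s = fit_similarity_landmarks(src, dst)
        pts = rng.uniform(-5, 5, (20, 3))
        assert np.abs(s.inverse().apply(s.apply(pts)) - pts).max() < 1e-12


class TestFFDEvaluation:
    def test_partition_of_unity_zero_field(self, rng):
        g = FFDGrid.covering((0, 0, 0), (20, 20, 20), 5.0)
        pts = rng.uniform(1, 19, (50, 3))
        assert np.abs(ffd_transform(g, pts) - pts).max() == 0.0

    def test_partition_of_unity_constant_field(self, rng):
        g = FFDGrid.covering((0, 0, 0), (20, 20, 20), 5.0)
        g.disp[...] = [1.0, -2.0, 0.5]
        pts = rng.uniform(1, 19, (50, 3))
        assert np.abs(ffd_transform(g, pts) - pts - [1.0, -2.0, 0.5]).max() < 1e-12

    def test_matches_brute_force(self, rng):
        g = random_grid(rng)
        pts = rng.uniform(1, 19, (40, 3))
        vec = ffd_displacement(g, pts)
        for i in range(len(pts)):
            assert np.abs(vec[i] - bspline_eval_brute(g, pts[i])).max() < 1e-9

    def test_locality(self, rng):
        """A single control point only affects its 4-delta support cube."""
        g = FFDGrid.covering((0, 0, 0), (30, 30, 30), 5.0)
        g.disp[4, 4, 4, 1] = 1.0
        node = g.origin + 4 * g.spacing
        pts = rng.uniform(1, 29, (300, 3))
        outside = np.abs(pts - node).max(axis=1) >= 2 * g.spacing
        disp = ffd_displacement(g, pts)
        assert np.abs(disp[outside]).max() == 0.0
        assert np.abs(disp[~outside]).max() > 0.0

    def test_point_outside_support_raises(self):
        g = FFDGrid.covering((0, 0, 0), (20, 20, 20), 5.0)
        with pytest.raises(ValueError, match="outside"):
            ffd_transform(g, np.array([[200.0, 0.0, 0.0]]))


class TestBasisProperties:
    @given(st.floats(min_value=0.0, max_value=1.0, exclude_max=True))
    @settings(max_examples=200, deadline=None)
    def test_partition_of_unity_and_positivity(self, u):
        w = bspline_weights(np.array(u))
        assert abs(w.sum() - 1.0) < 1e-12
        assert np.all(w >= 0.0)

    @given(st.floats(min_value=0.0, max_value=1.0, exclude_max=True))
    @settings(max_examples=50, deadline=None)
    def test_linear_precision(self, u):
        """Cubic B-splines reproduce linear functions of the knot index."""
        w = bspline_weights(np.array(u))
        nodes = np.arange(-1.0, 3.0)
        assert abs(float(w @ nodes) - u) < 1e-12


class TestScatteredFit:
    def test_constant_displacement_reproduced(self, rng):
        lat = FFDGrid.covering((0, 0, 0), (20, 20, 20), 5.0)
        pts = rng.uniform(0.5, 19.5, (2000, 3))
        v = np.array([0.5, -0.2, 0.1])
        fit, rms = fit_ffd_scattered(pts, np.tile(v, (len(pts), 1)), lat,
                                     ridge=1e-10)
        probe = rng.uniform(2, 18, (200, 3))
        assert np.abs(ffd_displacement(fit, probe) - v).max() < 1e-6
        assert rms < 1e-6

    def test_construct_and_recover_field(self, rng):
        truth = random_grid(rng)
        pts = rng.uniform(0.5, 19.5, (4000, 3))
        d = ffd_displacement(truth, pts)
        fit, _ = fit_ffd_scattered(pts, d, FFDGrid.covering((0, 0, 0),
                                                            (20, 20, 20), 5.0),
                                   ridge=1e-8)
        probe = rng.uniform(2, 18, (300, 3))
        err = np.abs(ffd_displacement(fit, probe) - ffd_displacement(truth, probe))
        assert err.max() < 1e-3

    def test_single_point_minimum_norm(self):
        lat = FFDGrid.covering((0, 0, 0), (20, 20, 20), 5.0)
        fit, rms = fit_ffd_scattered(np.array([[10.0, 10.0, 10.0]]),
                                     np.array([[1.0, 0.0, 0.0]]), lat)
        val = ffd_displacement(fit, np.array([[10.0, 10.0, 10.0]]))[0]
        assert abs(val[0] - 1.0) < 1e-3
        assert abs(val[1]) < 1e-9 and abs(val[2]) < 1e-9

    def test_empty_input_rejected(self):
        lat = FFDGrid.covering((0, 0, 0), (20, 20, 20), 5.0)
        with pytest.raises(ValueError, match="no points"):
            fit_ffd_scattered(np.empty((0, 3)), np.empty((0, 3)), lat)


class TestRefinement:
    def test_subdivision_is_exact(self, rng):
        g = random_grid(rng, zero_border=True)
        f = subdivide_ffd(g)
        pts = rng.uniform(2, 18, (400, 3))
        assert np.abs(ffd_displacement(g, pts) - ffd_displacement(f, pts)).max() < 1e-12

    def test_refine_approximates_field(self, rng):
        g = random_grid(rng, zero_border=True)
        f = refine_ffd(g, 2.5)
        pts = rng.uniform(3, 17, (400, 3))
        dev = np.abs(ffd_displacement(f, pts) - ffd_displacement(g, pts)).max()
        assert dev < 0.10 * g.max_displacement()

    def test_zero_and_constant_fields_preserved(self, rng):
        g = FFDGrid.covering((0, 0, 0), (40, 40, 40), 20.0)
        assert refine_ffd(g, 10.0).max_displacement() == 0.0
        g.disp[...] = [2.0, 0.0, -1.0]
        f = refine_ffd(g, 10.0)
        pts = rng.uniform(5, 35, (100, 3))
        assert np.abs(ffd_displacement(f, pts) - [2.0, 0.0, -1.0]).max() < 1e-9

    def test_coarser_spacing_rejected(self):
        g = FFDGrid.covering((0, 0, 0), (20, 20, 20), 5.0)
        with pytest.raises(ValueError, match="smaller"):
            refine_ffd(g, 10.0)


def _sphere_points(n, radius, rng):
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return radius * v


class TestNonRigidICP:
    def test_identical_surfaces_zero_rmse(self, rng):
        pts = _sphere_points(800, 10.0, rng)
        res = NonRigidICP(pts, pts, schedule_mm=(20.0, 10.0), max_iter=5).fit()
        assert res.rmse_mm[-1] < 1e-9

    def test_recovers_smooth_warp(self, rng):
        """Construct-and-recover: a known smooth warp is undone by ICP."""
        pts = _sphere_points(2500, 10.0, rng)
        truth = FFDGrid.covering((-14, -14, -14), (14, 14, 14), 10.0)
        d = rng.uniform(-2, 2, truth.disp.shape)
        d[:2] = d[-2:] = 0
        d[:, :2] = d[:, -2:] = 0
        d[:, :, :2] = d[:, :, -2:] = 0
        truth.disp = d
        warped = pts + ffd_displacement(truth, pts, extend_zero=True)
        res = NonRigidICP(warped, pts, schedule_mm=(20.0, 10.0, 5.0, 3.0),
                          max_iter=12).fit()
        assert res.final_rmse_mm < 0.5
        assert res.final_rmse_mm < 0.2 * res.initial_rmse_mm
        assert all(a >= b - 1e-6 for a, b in zip(res.rmse_mm, res.rmse_mm[1:]))

    def test_non_overlapping_rejected(self, rng):
        a = _sphere_points(300, 5.0, rng)
        with pytest.raises(ValueError, match="overlap"):
            NonRigidICP(a, a + 500.0, schedule_mm=(20.0,), max_iter=2).fit()

    def test_translation_equivariance(self, rng):
        """Translating both meshes translates the recovered deformation."""
        pts = _sphere_points(800, 8.0, rng)
        truth = FFDGrid.covering((-12, -12, -12), (12, 12, 12), 10.0)
        d = rng.uniform(-1.5, 1.5, truth.disp.shape)
        d[:2] = d[-2:] = 0
        d[:, :2] = d[:, -2:] = 0
        d[:, :, :2] = d[:, :, -2:] = 0
        truth.disp = d
        warped = pts + ffd_displacement(truth, pts, extend_zero=True)
        t = np.array([7.0, -3.0, 2.0])
        res1 = NonRigidICP(warped, pts, schedule_mm=(20.0, 10.0), max_iter=6).fit()
        res2 = NonRigidICP(warped + t, pts + t, schedule_mm=(20.0, 10.0),
                           max_iter=6).fit()
        out1 = warped + ffd_displacement(res1.final_ffd, warped, extend_zero=True)
        out2 = (warped + t) + ffd_displacement(res2.final_ffd, warped + t,
                                               extend_zero=True)
        assert np.abs(out2 - (out1 + t)).max() < 1e-6

    def test_summary_mentions_levels(self, rng):
        pts = _sphere_points(500, 8.0, rng)
        res = NonRigidICP(pts, pts, schedule_mm=(20.0, 10.0), max_iter=2).fit()
        text = res.summary()
        assert "RMSE" in text and "20.00" in text
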