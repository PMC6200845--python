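"""Dual-Kriging fit/apply, morph quality and control-point elimination."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from cortimap.kriging import (
    KrigingError,
    KrigingModel,
    apply_kriging,
    covariance,
    fit_kriging,
    morph_quality,
    optimize_control_points,
)
from cortimap.mesh import LandmarkSet
from cortimap.fixtures import FixtureSpec, make_target_pair
from conftest import outer_nodes


def random_points(n, seed, scale=20.0):
    return np.random.default_rng(seed).uniform(-scale, scale, size=(n, 3))


class TestCovariance:
    @pytest.mark.parametrize(
        "h,expected",
        [(1.0, 0.0), (0.0, 0.0), (np.e, np.e**2)],
    )
    def test_logarithmic_values(self, h, expected):
        assert covariance(h, "log") == pytest.approx(expected, abs=1e-12)

    def test_optional_kinds(self):
        assert covariance(2.0, "linear") == 2.0
        assert covariance(2.0, "cubic") == 8.0
        assert covariance(0.0, "gaussian") == 1.0
        assert covariance(0.0, "multiquadric", scale=1.0) == 1.0
        assert covariance(0.0, "inverse_multiquadric", scale=1.0) == 1.0

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            covariance(-0.1)


class TestFit:
    def test_identity_correspondence_gives_identity_map(self):
        pts = random_points(12, seed=0)
        model = fit_kriging(pts, pts)
        assert np.abs(model.fluctuation).max() < 1e-9
        drift = model.drift
        np.testing.assert_allclose(drift[1:], np.eye(3), atol=1e-9)
        np.testing.assert_allclose(drift[0], 0.0, atol=1e-8)

    def test_affine_correspondence_absorbed_by_drift(self):
        rng = np.random.default_rng(42)
        pts = random_points(15, seed=1)
        A = np.eye(3) + rng.normal(scale=0.2, size=(3, 3))
        c = rng.normal(scale=10.0, size=3)
        model = fit_kriging(pts, pts @ A.T + c)
        assert np.abs(model.fluctuation).max() < 1e-8
        probes = random_points(100, seed=2, scale=40.0)
        expected = probes @ A.T + c
        got = apply_kriging(model, probes)
        np.testing.assert_allclose(got, expected, rtol=1e-6, atol=1e-6)

    def test_exact_interpolation_nonaffine(self):
        rng = np.random.default_rng(5)
        src = random_points(12, seed=3)
        tgt = src + rng.normal(scale=3.0, size=src.shape)
        model = fit_kriging(src, tgt)
        err = np.linalg.norm(apply_kriging(model, src) - tgt, axis=1)
        assert err.max() < 1e-8

    def test_side_conditions_hold(self):
        rng = np.random.default_rng(6)
        src = random_points(20, seed=7)
        tgt = src + rng.normal(scale=5.0, size=src.shape)
        model = fit_kriging(src, tgt)
        res = model.side_condition_residuals()
        assert res["sum_b"] < 1e-9
        assert res["sum_bx"] < 1e-9

    def test_translation_equivariance(self):
        rng = np.random.default_rng(8)
        src = random_points(10, seed=9)
        tgt = src + rng.normal(scale=2.0, size=src.shape)
        probes = random_points(30, seed=10)
        v = np.array([7.0, -13.0, 4.0])
        out1 = apply_kriging(fit_kriging(src, tgt), probes) + v
        out2 = apply_kriging(fit_kriging(src + v, tgt + v), probes + v)
        np.testing.assert_allclose(out1, out2, atol=1e-9 * 100)

    def test_normalized_solve_agrees_with_raw(self):
        rng = np.random.default_rng(11)
        src = random_points(14, seed=12, scale=80.0)
        tgt = src + rng.normal(scale=6.0, size=src.shape)
        probes = random_points(40, seed=13, scale=100.0)
        raw = apply_kriging(fit_kriging(src, tgt), probes)
        nrm = apply_kriging(fit_kriging(src, tgt, normalize=True), probes)
        np.testing.assert_allclose(raw, nrm, atol=1e-6)

    def test_too_few_points_rejected(self):
        pts = random_points(4, seed=14)
        with pytest.raises(KrigingError, match="at least 5"):
            fit_kriging(pts, pts)

    def test_coplanar_points_rejected(self):
        pts = random_points(8, seed=15)
        pts[:, 2] = 0.0
        with pytest.raises(KrigingError, match="coplanar"):
            fit_kriging(pts, pts)

    def test_duplicate_points_rejected(self):
        pts = random_points(8, seed=16)
        pts[3] = pts[0]
        with pytest.raises(KrigingError, match="duplicat"):
            fit_kriging(pts, pts)

    def test_fit_on_fixture_landmarks_tracks_true_deformation(
        self, ellipsoid_spec, ellipsoid_shell, ellipsoid_pair
    ):
        layer, _ = ellipsoid_shell
        pair = ellipsoid_pair
        model = KrigingModel.fit(pair.landmarks_source, pair.landmarks_target)
        _, xyz = outer_nodes(layer)
        morphed = model(xyz)
        truth = pair.gt_morphed_source(xyz)
        err = np.linalg.norm(morphed - truth, axis=1).mean()
        lm = pair.landmarks_source.coords
        d = cdist(lm, lm)
        np.fill_diagonal(d, np.inf)
        spacing = d.min(axis=1).mean()
        assert err < spacing / 10.0


class TestMorphQuality:
    def test_identical_meshes_score_zero(self, ellipsoid_pair):
        nodes = ellipsoid_pair.target_mesh.coords
        lm = ellipsoid_pair.landmarks_target.coords
        q = morph_quality(nodes, nodes, lm, lm)
        assert q.mean == 0.0 and q.max == 0.0 and q.rmse == 0.0

    def test_matches_brute_force_all_pairs(self, ellipsoid_pair):
        rng = np.random.default_rng(17)
        morphed = ellipsoid_pair.target_mesh.coords + rng.normal(
            scale=1.0, size=ellipsoid_pair.target_mesh.coords.shape
        )
        target = ellipsoid_pair.target_mesh.coords
        lm_m = morphed[:24]
        lm_t = target[:24]
        q = morph_quality(morphed, target, lm_m, lm_t)
        brute = cdist(target, morphed).min(axis=1)
        np.testing.assert_allclose(q.q_values, brute, atol=1e-12)
        assert q.mean == pytest.approx(brute.mean())
        assert q.max == pytest.approx(brute.max())
        rmse = np.sqrt(np.mean(np.sum((lm_m - lm_t) ** 2, axis=1)))
        assert q.rmse == pytest.approx(rmse)
        assert q.max >= q.mean >= 0.0


class TestOptimization:
    def test_affine_correspondence_removes_nothing(self):
        spec = FixtureSpec(seed=3, deformation="affine")
        pair = make_target_pair(spec)
        src, tgt, rep = optimize_control_points(
            pair.landmarks_source, pair.landmarks_target
        )
        assert rep.rounds == []
        assert len(src) == len(pair.landmarks_source)
        assert rep.final_rmse == pytest.approx(0.0, abs=1e-8)

    def test_outlier_removed_first_round(self):
        spec = FixtureSpec(seed=7, outlier=(5, 10.0))
        pair = make_target_pair(spec)
        src, tgt, rep = optimize_control_points(
            pair.landmarks_source, pair.landmarks_target
        )
        assert rep.rounds, "outlier should trigger at least one elimination"
        assert rep.rounds[0].removed_index == 5
        assert rep.rounds[0].rmse < rep.initial_rmse

    def test_rmse_trace_monotone(self):
        spec = FixtureSpec(seed=11, noise_sd=1.0, outlier=(2, 12.0))
        pair = make_target_pair(spec)
        _, _, rep = optimize_control_points(
            pair.landmarks_source, pair.landmarks_target
        )
        trace = [rep.initial_rmse] + [r.rmse for r in rep.rounds]
        assert all(a > b for a, b in zip(trace, trace[1:]))
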