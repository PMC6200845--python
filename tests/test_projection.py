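"""Beta-weighted projection, accuracy/smoothness metrics, beta sweep."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from cortimap.mesh import NodalScalarField, SurfaceMesh
from cortimap.projection import (
    accuracy,
    beta_sweep,
    local_regression_error,
    local_regression_errors,
    project_thickness,
    smoothness,
)
from cortimap.kriging import KrigingModel
from cortimap.thickness import nodal_thickness
from cortimap.fixtures import (
    FixtureSpec,
    analytic_thickness_at,
    make_solid_shell,
    make_target_pair,
)
from conftest import outer_nodes


def simple_targets(n=5, seed=0):
    return np.random.default_rng(seed).uniform(-5, 5, size=(n, 3))


class TestProjectThickness:
    def test_beta_zero_is_plain_source_mean(self):
        src = np.array([[0, 0, 0], [5, 0, 0], [0, 9, 0]], float)
        res = project_thickness(simple_targets(), src, [1.0, 2.0, 3.0], 0.0)
        np.testing.assert_array_equal(res.values, 2.0)

    def test_coincident_node_takes_source_value(self):
        src = np.array([[1, 2, 3], [4, 5, 6]], float)
        tgt = np.array([[1, 2, 3], [0, 0, 0]], float)
        res = project_thickness(tgt, src, [1.5, 9.0], 4.0)
        assert res.values[0] == 1.5

    def test_hand_evaluated_weights(self):
        # sources at distances 1 and 2, thicknesses 1 and 3, beta = 1:
        # (1*1 + 3*0.5) / 1.5 = 5/3
        src = np.array([[1, 0, 0], [2, 0, 0]], float)
        tgt = np.array([[0, 0, 0]], float)
        res = project_thickness(tgt, src, [1.0, 3.0], 1.0)
        assert res.values[0] == pytest.approx(5.0 / 3.0, abs=1e-12)

    def test_negative_beta_rejected(self):
        with pytest.raises(ValueError):
            project_thickness(simple_targets(), simple_targets(3, 1), [1, 2, 3], -1.0)

    def test_empty_source_rejected(self):
        with pytest.raises(Exception):
            project_thickness(simple_targets(), np.empty((0, 3)), [], 2.0)

    def test_convex_combination_bounds(self, ellipsoid_pair, ellipsoid_shell):
        layer, _ = ellipsoid_shell
        ids, xyz = outer_nodes(layer)
        t = nodal_thickness(layer).field.reindex(ids)
        for beta in (0.0, 1.0, 4.0, 50.0):
            res = project_thickness(ellipsoid_pair.target_mesh, xyz, t, beta)
            assert res.values.min() >= t.min() - 1e-12
            assert res.values.max() <= t.max() + 1e-12

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        src = rng.uniform(-10, 10, size=(40, 3))
        t = rng.uniform(1, 3, size=40)
        tgt = rng.uniform(-10, 10, size=(25, 3))
        perm = rng.permutation(40)
        a = project_thickness(tgt, src, t, 4.0).values
        b = project_thickness(tgt, src[perm], t[perm], 4.0).values
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        src = rng.uniform(-10, 10, size=(30, 3))
        t = rng.uniform(1, 3, size=30)
        tgt = rng.uniform(-10, 10, size=(20, 3))
        a = project_thickness(tgt, src, t, 3.0).values
        b = project_thickness(17.0 * tgt, 17.0 * src, t, 3.0).values
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_large_beta_matches_nearest_neighbour(self, ellipsoid_shell):
        # well-separated regime: each target sits much closer to one source
        # node than to any other, so the beta = 50 weights are one-hot
        layer, _ = ellipsoid_shell
        ids, xyz = outer_nodes(layer)
        t = nodal_thickness(layer).field.reindex(ids)
        rng = np.random.default_rng(21)
        tgt = xyz + rng.normal(scale=0.3, size=xyz.shape)
        res = project_thickness(tgt, xyz, t, 50.0)
        _, nn = cKDTree(xyz).query(tgt)
        match = np.isclose(res.values, t[nn], rtol=1e-6, atol=1e-9)
        assert match.mean() >= 0.99

    def test_overflow_safe_at_extreme_beta(self):
        src = np.array([[0, 0, 0], [1000.0, 0, 0]], float)
        tgt = np.array([[1.0, 0, 0]], float)
        res = project_thickness(tgt, src, [2.0, 9.0], 500.0)
        assert np.isfinite(res.values).all()
        assert res.values[0] == pytest.approx(2.0)


class TestAccuracy:
    def test_endpoint_anchors(self):
        t0 = np.array([2.0, 2.0, 2.0])
        tm = np.array([1.0, 2.0, 3.0])
        assert accuracy(t0, t0, tm) == 0.0
        assert accuracy(tm, t0, tm) == 1.0

    def test_hand_computed_value(self):
        tm = np.array([1.0, 2.0, 3.0])
        t0 = np.array([2.0, 2.0, 2.0])
        tb = np.array([1.5, 2.0, 2.5])
        assert accuracy(tb, t0, tm) == pytest.approx(0.75)

    def test_constant_source_warns_and_returns_one(self):
        t = np.array([2.0, 2.0])
        with pytest.warns(UserWarning):
            assert accuracy(t, t, t) == 1.0


class TestLocalRegression:
    def test_constant_field_zero_everywhere(self, ellipsoid_pair):
        mesh = ellipsoid_pair.target_mesh
        f = NodalScalarField(mesh.node_ids, np.full(mesh.n_nodes, 1.77))
        E = local_regression_errors(mesh, f)
        assert np.abs(E.values).max() < 1e-12

    def test_linear_field_zero(self, ellipsoid_pair):
        mesh = ellipsoid_pair.target_mesh
        vals = mesh.coords @ np.array([0.1, -0.2, 0.05]) + 2.0
        E = local_regression_errors(mesh, NodalScalarField(mesh.node_ids, vals))
        assert np.abs(E.values).max() < 1e-12

    def test_matches_normal_equations_oracle(self):
        # 5 hand-placed neighbours around a hub node
        coords = np.array(
            [
                [0, 0, 0],       # hub (node 1)
                [1, 0, 0.1], [0, 1, -0.2], [-1, 0.5, 0], [0.3, -1, 0.4],
                [1, 1, 0.3],
            ],
            float,
        )
        faces = [(1, 2, 3), (1, 3, 4), (1, 4, 5), (1, 5, 6), (1, 6, 2)]
        mesh = SurfaceMesh(np.arange(1, 7), coords, faces)
        vals = np.array([2.0, 1.1, 0.7, 2.5, 1.9, 0.4])
        f = NodalScalarField(mesh.node_ids, vals)
        E1 = local_regression_error(mesh, f, 1)
        rows = [1, 2, 3, 4, 5]  # nodes 2..6, edge-connected to node 1
        X = np.column_stack([coords[rows], np.ones(5)])
        t = vals[rows]
        c = np.linalg.solve(X.T @ X, X.T @ t)  # independent normal equations
        resid = X @ c - t
        assert E1 > 0
        assert E1 == pytest.approx(float(resid @ resid), abs=1e-9)

    def test_full_field_matches_oracle(self, ellipsoid_pair, ellipsoid_shell):
        layer, _ = ellipsoid_shell
        ids, xyz = outer_nodes(layer)
        t = nodal_thickness(layer).field.reindex(ids)
        mesh = ellipsoid_pair.target_mesh
        proj = project_thickness(mesh, xyz, t, 4.0)
        E = local_regression_errors(mesh, proj.field)
        from cortimap.mesh import node_adjacency

        adj = node_adjacency(mesh)
        for nid in mesh.node_ids[:50]:
            nbrs = adj[int(nid)]
            X = np.column_stack(
                [mesh.coords[mesh.index_of(nbrs)], np.ones(len(nbrs))]
            )
            tv = proj.field.reindex(nbrs)
            c = np.linalg.solve(X.T @ X, X.T @ tv)
            resid = X @ c - tv
            assert E[int(nid)] == pytest.approx(float(resid @ resid), abs=1e-9)


class TestSmoothness:
    def test_endpoint_anchors(self):
        e0 = np.zeros(3)
        em = np.array([1.0, 2.0, 0.5])
        assert smoothness(e0, e0, em) == 0.0
        assert smoothness(em, e0, em) == 1.0

    def test_hand_computed_value(self):
        e0 = np.array([0.0, 0.0])
        eb = np.array([1.0, 1.0])
        em = np.array([2.0, 2.0])
        # printed-formula ratio 2/8; reported S = 1 - 0.25
        assert smoothness(eb, e0, em) == pytest.approx(0.75)

    def test_zero_denominator_warns(self):
        e = np.array([0.5, 0.5])
        with pytest.warns(UserWarning):
            assert smoothness(e, e, e) == 1.0


@pytest.fixture(scope="module")
def sweep(ellipsoid_pair, ellipsoid_shell):
    layer, _ = ellipsoid_shell
    ids, xyz = outer_nodes(layer)
    t = nodal_thickness(layer).field.reindex(ids)
    return beta_sweep(ellipsoid_pair.target_mesh, xyz, t)


class TestBetaSweep:
    def test_anchor_values(self, sweep):
        assert sweep.A[0] == 0.0 and sweep.S[0] == 0.0
        assert sweep.A[-1] == 1.0 and sweep.S[-1] == 1.0

    def test_monotone_trends(self, sweep):
        assert np.all(np.diff(sweep.A) >= -1e-9)
        assert np.all(np.diff(sweep.S) >= -1e-9)  # noisiness grows with beta

    def test_crossing_is_interior(self, sweep):
        assert 0.0 < sweep.selected_beta < 50.0
        # at the crossing, A equals the falling smoothness curve 1 - S
        g = sweep.A - (1.0 - sweep.S)
        assert g[0] < 0 < g[-1]

    def test_two_point_grid_interpolates_single_crossing(
        self, ellipsoid_pair, ellipsoid_shell
    ):
        layer, _ = ellipsoid_shell
        ids, xyz = outer_nodes(layer)
        t = nodal_thickness(layer).field.reindex(ids)
        sw = beta_sweep(
            ellipsoid_pair.target_mesh, xyz, t, betas=(0.0, 50.0), beta_max=50.0
        )
        # two straight lines from (0,0)-(50,1) and (0,1)-(50,0) cross at 25
        assert sw.selected_beta == pytest.approx(25.0)

    def test_grid_must_contain_zero_and_anchor(self, ellipsoid_pair):
        with pytest.raises(ValueError):
            beta_sweep(
                ellipsoid_pair.target_mesh,
                np.zeros((3, 3)),
                [1, 2, 3],
                betas=(1.0, 50.0),
            )

    def test_parameter_recovery_improves_with_refinement(self):
        rmses = []
        for level in (1, 2, 3):
            spec = FixtureSpec(level=level, target_level=level, seed=1)
            layer, _ = make_solid_shell(spec)
            pair = make_target_pair(spec)
            ids, xyz = outer_nodes(layer)
            t = nodal_thickness(layer).field.reindex(ids)
            model = KrigingModel.fit(pair.landmarks_source, pair.landmarks_target)
            proj = project_thickness(pair.target_mesh, model(xyz), t, 4.0)
            truth = analytic_thickness_at(spec, pair.gt_target_preimage)
            rmses.append(float(np.sqrt(np.mean((proj.values - truth) ** 2))))
        assert rmses[0] > rmses[1] > rmses[2]
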