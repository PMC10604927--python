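"""Polygon tracking: bandwidths, mean shift, ordering, penalized optimization.

The objective terms (Delta, MP, CP, lambda, G, G') are checked against the
brute-force oracles in tests/oracles.py, which use exact point-to-segment
distances and plain loops.
"""

import numpy as np
import pytest

import oracles
from kidseg.aspt import (
    ASPTConfig,
    PolygonalCurve,
    VertexOptState,
    VertexSequence,
    _objective_arrays,
    adaptive_bandwidths,
    avg_sq_distance,
    curvature_penalty_cp,
    curvature_penalty_mp,
    data_radius,
    mean_shift_modes,
    optimize_vertices,
    order_vertices,
    penalized_distance,
    penalty_lambda,
    run_aspt,
    total_objective,
)
from kidseg.geometry import dsc, rasterize_polygon, denormalize


def random_instance(rng, n_points=50, n_vertices=5):
    pts = rng.uniform(-1, 1, size=(n_points, 2))
    theta = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    theta += np.linspace(0, 1e-3, n_vertices)  # enforce distinct vertices
    verts = np.column_stack([0.8 * np.cos(theta), 0.8 * np.sin(theta)])
    return pts, verts


class TestDataRadius:
    def test_square_symmetry(self):
        pts = np.array([[0, 0], [2, 0], [0, 2], [2, 2]], float)
        assert data_radius(pts) == pytest.approx(np.sqrt(2))

    def test_identical_points_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert data_radius(np.ones((4, 2))) == 0.0

    def test_matches_brute_force(self, rng):
        pts = rng.normal(size=(100, 2))
        c = pts.mean(axis=0)
        expected = max(float(np.hypot(*(p - c))) for p in pts)
        assert data_radius(pts) == pytest.approx(expected, abs=1e-12)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            data_radius(np.array([[1.0, 2.0]]))


class TestAdaptiveBandwidths:
    def test_collinear_unit_spacing(self):
        pts = np.array([[0, 0], [1, 0], [2, 0]], float)
        np.testing.assert_allclose(adaptive_bandwidths(pts, 1), [1, 1, 1])
        np.testing.assert_allclose(adaptive_bandwidths(pts, 2), [2, 1, 2])

    def test_uniform_grid_interior_constant(self):
        xx, yy = np.mgrid[0:6, 0:6]
        pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
        h = adaptive_bandwidths(pts, 4)
        interior = [(x, y) for x in range(1, 5) for y in range(1, 5)]
        vals = {h[i] for i, p in enumerate(pts) if tuple(p) in interior}
        assert vals == {1.0}

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError, match="k_neighbors"):
            adaptive_bandwidths(np.zeros((3, 2)), 3)

    def test_all_identical_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            adaptive_bandwidths(np.ones((5, 2)), 2)


class TestMeanShiftModes:
    def test_single_blob_one_mode_matches_kde_argmax(self, rng):
        pts = rng.normal(0.0, 0.05, size=(100, 2))
        h = adaptive_bandwidths(pts, 10)
        modes, labels = mean_shift_modes(pts, h, tol=1e-6)
        assert len(modes) == 1
        oracle = oracles.kde_grid_argmax(pts, h, -0.3, 0.3, n_grid=121)
        assert np.linalg.norm(modes[0] - oracle) < np.median(h) / 10 + 0.3 / 120

    def test_two_separated_blobs(self, rng):
        a = rng.normal(0.0, 0.03, size=(60, 2))
        b = rng.normal(0.0, 0.03, size=(60, 2)) + [1.5, 0.0]
        pts = np.vstack([a, b])
        h = adaptive_bandwidths(pts, 10)
        modes, labels = mean_shift_modes(pts, h, tol=1e-6)
        assert len(modes) == 2
        # labels agree with blob membership
        first, second = labels[:60], labels[60:]
        assert len(set(first.tolist())) == 1 and len(set(second.tolist())) == 1
        assert first[0] != second[0]

    def test_one_point(self):
        modes, labels = mean_shift_modes(np.array([[0.3, 0.4]]), 0.1)
        np.testing.assert_allclose(modes, [[0.3, 0.4]])
        assert labels.tolist() == [0]

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            mean_shift_modes(np.zeros((3, 2)), -1.0)
        with pytest.raises(ValueError):
            mean_shift_modes(np.zeros((3, 2)), 1.0, tol=0.0)


class TestOrderVertices:
    def test_shuffled_square_recovers_ccw(self):
        square = np.array([[1, 1], [-1, 1], [1, -1], [-1, -1]], float)
        curve = order_vertices(square)
        # counter-clockwise in the (x, y) frame: positive shoelace area
        from kidseg.geometry import polygon_area

        assert polygon_area(curve.vertices) > 0
        assert len(curve) == 4

    def test_circle_order_recovered(self, rng):
        theta = np.linspace(0, 2 * np.pi, 12, endpoint=False)
        modes = np.column_stack([np.cos(theta), np.sin(theta)])
        perm = rng.permutation(12)
        curve = order_vertices(modes[perm])
        angles = np.arctan2(curve.vertices[:, 1], curve.vertices[:, 0])
        rolled = np.roll(angles, -int(np.argmin(angles)))
        assert (np.diff(rolled) > 0).all()

    def test_collinear_flagged(self):
        with pytest.warns(UserWarning, match="degenerate"):
            order_vertices(np.array([[0, 0], [1, 0], [2, 0]], float))

    def test_too_few_modes(self):
        with pytest.raises(ValueError, match="insufficient"):
            order_vertices(np.array([[0, 0], [1, 1]], float))


class TestObjectiveTermsAgainstOracles:
    def test_delta_matches_brute_force(self, rng):
        pts, verts = random_instance(rng, n_points=50, n_vertices=5)
        state = VertexOptState(pts, PolygonalCurve(verts), data_radius(pts))
        for i in range(len(verts)):
            assert avg_sq_distance(state, i) == pytest.approx(
                oracles.delta(pts, verts, i), abs=1e-10
            )

    def test_on_curve_data_gives_zero_delta(self):
        verts = np.array([[0, 0], [2, 0], [2, 2], [0, 2]], float)
        # data points exactly on the polygon edges (segment midpoints)
        pts = np.array([[1, 0], [2, 1], [1, 2], [0, 1]], float)
        state = VertexOptState(pts, PolygonalCurve(verts), 1.0)
        for i in range(4):
            assert avg_sq_distance(state, i) == pytest.approx(
                oracles.delta(pts, verts, i), abs=1e-12
            )
            assert avg_sq_distance(state, i) == pytest.approx(0.0, abs=1e-12)

    def test_isolated_vertex_tau(self):
        # a point beyond a corner projects onto the vertex: tau = d^2
        verts = np.array([[0, 0], [2, 0], [2, 2], [0, 2]], float)
        pts = np.array([[-0.3, -0.4]])  # distance 0.5 from vertex 0
        state = VertexOptState(pts, PolygonalCurve(verts), 1.0)
        assert avg_sq_distance(state, 0) == pytest.approx(0.25)

    def test_mp_matches_brute_force(self, rng):
        pts, verts = random_instance(rng, n_points=80, n_vertices=7)
        state = VertexOptState(pts, PolygonalCurve(verts), data_radius(pts))
        for i in range(len(verts)):
            assert curvature_penalty_mp(state, i) == pytest.approx(
                oracles.mp(pts, verts, i), abs=1e-10
            )

    def test_mp_square_with_on_edge_points(self):
        verts = np.array([[0, 0], [2, 0], [2, 2], [0, 2]], float)
        pts = np.array(
            [[0.5, 0], [1.5, 0], [2, 0.5], [2, 1.5], [1.5, 2], [0.5, 2], [0, 1.5], [0, 0.5]]
        )
        state = VertexOptState(pts, PolygonalCurve(verts), 1.0)
        for i in range(4):
            assert curvature_penalty_mp(state, i) == pytest.approx(
                oracles.mp(pts, verts, i), abs=1e-12
            )

    def test_cp_angles(self):
        r = 1.0
        verts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)  # right angles
        state = VertexOptState(verts + 0.0, PolygonalCurve(verts), r)
        for i in range(4):
            assert curvature_penalty_cp(state, i) == pytest.approx(1.0)  # gamma = pi/2
        spike = np.array([[1, 0.001], [0, 0], [1, -0.001], [3, 0.0]])  # gamma ~ 0 at v1
        state2 = VertexOptState(spike, PolygonalCurve(spike), r)
        assert curvature_penalty_cp(state2, 1) == pytest.approx(2.0, abs=1e-5)

    def test_cp_straight_angle_zero(self):
        verts = np.array([[0, 0], [1, 0], [2, 0], [1, 1.0]])
        state = VertexOptState(verts, PolygonalCurve(verts), 1.0)
        assert curvature_penalty_cp(state, 1) == pytest.approx(0.0, abs=1e-12)

    def test_lambda_formula(self, rng):
        pts, verts = random_instance(rng, n_points=60, n_vertices=8)
        r = data_radius(pts)
        state = VertexOptState(pts, PolygonalCurve(verts), r)
        assert penalty_lambda(state) == pytest.approx(
            oracles.lam(pts, verts, r), abs=1e-10
        )
        state0 = VertexOptState(pts, PolygonalCurve(verts), r, lambda_prime=0.0)
        assert penalty_lambda(state0) == 0.0

    def test_lambda_arithmetic_example(self):
        # iv = 8, mean Delta = 0.04, r = 1 -> lambda = 0.13 * 2 * 0.2 = 0.052
        assert 0.13 * 8 ** (1 / 3) * np.sqrt(0.04) / 1.0 == pytest.approx(0.052)

    def test_penalized_distance_terms(self, rng):
        pts, verts = random_instance(rng, n_points=70, n_vertices=6)
        r = data_radius(pts)
        state = VertexOptState(pts, PolygonalCurve(verts), r)
        for i in range(len(verts)):
            assert penalized_distance(state, i, "mp") == pytest.approx(
                oracles.g_prime(pts, verts, i, r), abs=1e-10
            )
            assert penalized_distance(state, i, "cp") == pytest.approx(
                oracles.g_classic(pts, verts, i, r), abs=1e-10
            )

    def test_lambda_zero_decouples_penalty(self, rng):
        pts, verts = random_instance(rng)
        r = data_radius(pts)
        state = VertexOptState(pts, PolygonalCurve(verts), r, lambda_prime=0.0)
        iv = len(verts)
        for i in range(iv):
            assert penalized_distance(state, i, "mp") == pytest.approx(
                avg_sq_distance(state, i) / iv, abs=1e-12
            )

    def test_unknown_penalty_rejected(self, rng):
        pts, verts = random_instance(rng)
        state = VertexOptState(pts, PolygonalCurve(verts), data_radius(pts))
        with pytest.raises(ValueError, match="penalty"):
            penalized_distance(state, 0, "bogus")

    def test_fast_objective_agrees_with_per_vertex_sum(self, rng):
        for n_v in (4, 7, 10):
            pts, verts = random_instance(rng, n_points=90, n_vertices=n_v)
            r = data_radius(pts)
            state = VertexOptState(pts, PolygonalCurve(verts), r)
            for penalty in ("mp", "cp"):
                fast = _objective_arrays(pts, verts, r, 0.13, penalty)
                slow = total_objective(state, penalty)
                assert fast == pytest.approx(slow, abs=1e-10)


class TestOptimizeVertices:
    def test_noisy_square_monotone_decrease(self, rng):
        t = rng.uniform(0, 4, size=200)
        side = np.floor(t).astype(int)
        frac = t - side
        base = np.array([[0, 0], [1, 0], [1, 1], [0, 1], [0, 0]], float)
        pts = base[side] + (base[side + 1] - base[side]) * frac[:, None]
        pts += rng.normal(0, 0.02, size=pts.shape)
        verts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float) + rng.normal(
            0, 0.05, size=(4, 2)
        )
        state = VertexOptState(pts, PolygonalCurve(verts), data_radius(pts))
        curve, trace = optimize_vertices(state, max_rounds=5, search_radius=0.15)
        assert all(b <= a + 1e-12 for a, b in zip(trace, trace[1:]))
        assert trace[-1] < trace[0]

    def test_huge_rel_tol_returns_initial_curve(self, rng):
        pts, verts = random_instance(rng)
        state = VertexOptState(pts, PolygonalCurve(verts.copy()), data_radius(pts))
        curve, trace = optimize_vertices(state, rel_tol=10.0)
        np.testing.assert_allclose(curve.vertices, verts)
        assert len(trace) == 1

    def test_data_on_polygon_is_near_fixed_point(self):
        verts = np.array([[0, 0], [2, 0], [2, 2], [0, 2]], float)
        t = np.linspace(0, 4, 80, endpoint=False)
        side = np.floor(t).astype(int)
        frac = t - side
        base = np.vstack([verts, verts[:1]])
        pts = base[side] + (base[side + 1] - base[side]) * frac[:, None]
        state = VertexOptState(pts, PolygonalCurve(verts.copy()), data_radius(pts))
        curve, trace = optimize_vertices(state, max_rounds=2, search_radius=0.05)
        assert np.abs(curve.vertices - verts).max() < 0.06


class TestVertexSequence:
    def test_strict_monotonicity_enforced(self):
        with pytest.raises(ValueError, match="increasing"):
            VertexSequence(t=np.array([0.0, 0.5, 0.5]), coords=np.zeros((3, 2)))

    def test_with_closure(self):
        seq = VertexSequence(
            t=np.array([0.0, 0.3, 0.6]), coords=np.array([[1, 2], [3, 4], [5, 6.0]])
        )
        closed = seq.with_closure()
        assert closed.t[-1] == 1.0
        np.testing.assert_allclose(closed.coords[-1], [1, 2])
        assert len(closed.with_closure()) == len(closed)


class TestRunASPT:
    def test_dense_circle(self):
        theta = np.linspace(0, 2 * np.pi, 120, endpoint=False)
        pts = np.column_stack([50 + 30 * np.cos(theta), 50 + 30 * np.sin(theta)])
        res = run_aspt(pts, ASPTConfig(k_neighbors=8, max_rounds=3))
        radii = np.linalg.norm(res.sequence.coords, axis=1)  # normalized: unit circle
        assert np.abs(radii - 1.0).max() < 0.02
        gaps = np.diff(np.append(res.sequence.t, 1.0))
        assert gaps.max() / gaps.mean() < 3.0  # no long unsampled arc
        assert res.report["n_modes"] >= 3

    def test_square_boundary_polygon_quality(self):
        side = np.linspace(10, 70, 40)
        pts = np.vstack(
            [
                np.column_stack([side, np.full_like(side, 10)]),
                np.column_stack([np.full_like(side, 70), side]),
                np.column_stack([side[::-1], np.full_like(side, 70)]),
                np.column_stack([np.full_like(side, 10), side[::-1]]),
            ]
        )
        truth = np.zeros((96, 96), bool)
        truth[10:71, 10:71] = True
        res = run_aspt(pts, ASPTConfig(k_neighbors=8, max_rounds=3))
        assert res.report["n_modes"] >= 4
        poly = denormalize(res.sequence.coords, res.transform)
        assert dsc(rasterize_polygon(poly, (96, 96)), truth) >= 0.95

    def test_ablation_configuration_matrix_runs(self):
        theta = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        pts = np.column_stack([40 + 25 * np.cos(theta), 40 + 20 * np.sin(theta)])
        for cfg in (
            ASPTConfig(fixed_bandwidth="median", penalty="cp", k_neighbors=8, max_rounds=2),
            ASPTConfig(fixed_bandwidth="median", penalty="mp", k_neighbors=8, max_rounds=2),
            ASPTConfig(penalty="cp", k_neighbors=8, max_rounds=2),
        ):
            res = run_aspt(pts, cfg)
            assert res.report["n_modes"] >= 3
            assert res.report["final_objective"] <= res.report["initial_objective"]

    def test_determinism(self):
        theta = np.linspace(0, 2 * np.pi, 90, endpoint=False)
        pts = np.column_stack([30 + 20 * np.cos(theta), 30 + 15 * np.sin(theta)])
        cfg = ASPTConfig(k_neighbors=8, max_rounds=2)
        a = run_aspt(pts, cfg)
        b = run_aspt(pts, cfg)
        np.testing.assert_array_equal(a.sequence.coords, b.sequence.coords)
        np.testing.assert_array_equal(a.sequence.t, b.sequence.t)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            run_aspt(np.array([[0, 0], [1, 1.0]]))
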