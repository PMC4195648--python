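"""Hybrid geodesic/local-region curve evolution: edge map, local means,
curvature, the evolution loop and its stopping rule."""

import numpy as np
import pytest

from adipoquant import (
    ContainmentLost,
    LevelSetField,
    SnakeParams,
    area_converged_at,
    curvature,
    edge_stop_map,
    evolve,
    local_mean_fields,
    local_means,
)
from adipoquant.contour import signed_distance
from conftest import circle_sdf


class TestEdgeStopMap:
    def test_constant_slice_gives_one(self):
        g = edge_stop_map(np.full((20, 20), 0.5))
        np.testing.assert_allclose(g, 1.0)

    def test_minimum_on_step_edge(self):
        img = np.zeros((20, 40))
        img[:, 20:] = 1.0
        g = edge_stop_map(img, edge_sigma=1.5)
        row = g[10]
        assert np.argmin(row) in (19, 20)
        assert row.min() < row[0] and row.min() < row[-1]

    def test_strictly_decreasing_in_gradient_magnitude(self):
        grads = np.array([0.0, 0.1, 0.3, 0.7])
        vals = 1.0 / (1.0 + grads**2)
        assert np.all(np.diff(vals) < 0)  # functional form check
        # and the map respects it on ramps of increasing slope
        outs = []
        for slope in (0.01, 0.05, 0.1):
            img = np.tile(np.arange(40) * slope, (20, 1))
            outs.append(edge_stop_map(img)[10, 20])
        assert np.all(np.diff(outs) < 0)


class TestLocalMeans:
    def test_two_tone_split_by_contour(self):
        img = np.full((40, 40), 0.2)
        img[:, :20] = 0.8
        phi = np.tile((np.arange(40) - 19.5), (40, 1))  # negative left = inside
        for point in [(10, 19), (20, 20), (30, 19)]:
            u, v = local_means(img, phi, point, 5)
            assert u == pytest.approx(0.8)
            assert v == pytest.approx(0.2)

    def test_radius_one_hand_enumeration(self):
        img = np.array(
            [[0.1, 0.2, 0.3], [0.4, 1.0, 0.6], [0.7, 0.8, 0.9]]
        )
        phi = np.array([[-1, -1, 1], [-1, 1, 1], [-1, 1, 1]], dtype=float)
        u, v = local_means(img, phi, (1, 1), 1)
        # ball: (0,1)in, (1,0)in, (1,1)out, (1,2)out, (2,1)out
        assert u == pytest.approx((0.2 + 0.4) / 2)
        assert v == pytest.approx((1.0 + 0.6 + 0.8) / 3)

    def test_uniform_image_equal_means(self):
        img = np.full((20, 20), 0.37)
        phi = circle_sdf((20, 20), (10, 10), 5)
        u, v = local_means(img, phi, (5, 10), 4)
        assert u == pytest.approx(v) == pytest.approx(0.37)

    def test_vectorized_fields_match_pointwise_enumeration(self):
        rng = np.random.default_rng(9)
        img = rng.random((30, 30))
        phi = circle_sdf((30, 30), (15, 15), 8)
        u_f, v_f = local_mean_fields(img, phi < 0, 4)
        for point in [(7, 15), (15, 7), (15, 23), (20, 20), (15, 15)]:
            u, v = local_means(img, phi, point, 4)
            assert u_f[point] == pytest.approx(u, abs=1e-9)
            assert v_f[point] == pytest.approx(v, abs=1e-9)


class TestCurvature:
    def test_circle_radius_20(self):
        phi = circle_sdf((128, 128), (64, 64), 20.0)
        k = curvature(phi)
        zero = np.abs(phi) < 0.5
        np.testing.assert_allclose(k[zero], 0.05, rtol=0.05)

    def test_straight_edge_zero(self):
        phi = np.tile(np.arange(40, dtype=float) - 19.5, (40, 1))
        k = curvature(phi)
        assert np.abs(k[5:-5, 5:-5]).max() < 1e-3

    def test_ellipse_extremes_match_closed_form(self):
        # curvature of a level curve is geometric: any smooth embedding with
        # the same zero set yields the ellipse's curvature on that set
        a, b = 40.0, 20.0
        yy, xx = np.mgrid[0:160, 0:160].astype(float)
        phi = ((yy - 80) / a) ** 2 + ((xx - 80) / b) ** 2 - 1.0
        k = curvature(phi)
        # vertex on the minor axis (flattest point): kappa = b/a^2
        assert k[80, 80 - int(b)] == pytest.approx(b / a**2, rel=0.05)
        # vertex on the major axis (sharpest point): kappa = a/b^2
        assert k[80 - int(a), 80] == pytest.approx(a / b**2, rel=0.05)
        assert k[80 - int(a), 80] > k[80, 80 - int(b)]


class TestStoppingRule:
    def test_recorded_area_sequence_halts_at_third_check(self):
        areas = (10_000, 10_210, 10_214)
        assert area_converged_at(areas, area_tol=10) == 2

    def test_no_convergence_returns_none(self):
        assert area_converged_at((100, 200, 300), 10) is None

    def test_first_qualifying_pair_wins(self):
        assert area_converged_at((100, 105, 300, 301), 10) == 1


class TestEvolve:
    def test_converges_on_dark_ring(self):
        # bright disc inside bright surround, separated by a dark ring (wall)
        yy, xx = np.mgrid[0:192, 0:192]
        r = np.hypot(yy - 96, xx - 96)
        img = np.full((192, 192), 0.8)
        img[(r >= 60) & (r <= 64)] = 0.2
        phi0 = LevelSetField(signed_distance(r <= 35))
        field, trace = evolve(img, phi0, SnakeParams(balloon_weight=0.3))
        assert trace.stop_reason == "area_converged"
        zero = np.abs(field.phi) < 0.71
        assert (np.abs(r[zero] - 60) <= 2).mean() >= 0.95

    def test_pure_curvature_flow_shrinks_at_analytic_rate(self):
        img = np.full((128, 128), 0.5)
        phi0 = LevelSetField(circle_sdf((128, 128), (64, 64), 40.0))
        params = SnakeParams(
            balloon_weight=0.0, curvature_weight=1.0, area_tol=1e-6,
            max_iters=60, check_interval=5, reinit_every=0,
        )
        _, trace = evolve(img, phi0, params)
        areas = np.array(trace.areas)
        rates = -np.diff(areas) / params.check_interval
        expected = 2 * np.pi * params.curvature_weight * params.dt
        np.testing.assert_allclose(rates.mean(), expected, rtol=0.15)
        assert np.all(np.diff(areas) < 0)

    def test_zero_max_iters_returns_input(self):
        img = np.full((64, 64), 0.5)
        phi0 = LevelSetField(circle_sdf((64, 64), (32, 32), 10.0))
        field, trace = evolve(img, phi0, SnakeParams(max_iters=0))
        np.testing.assert_array_equal(field.phi, phi0.phi)
        assert trace.stop_reason == "max_iters"
        assert trace.n_iters == 0

    def test_pure_inflation_grows_until_border_error(self):
        img = np.full((96, 96), 0.5)
        phi0 = LevelSetField(circle_sdf((96, 96), (48, 48), 10.0))
        params = SnakeParams(
            balloon_weight=1.0, curvature_weight=0.0, area_tol=1e-6, max_iters=500
        )
        with pytest.raises(ContainmentLost):
            evolve(img, phi0, params)

    def test_inflation_area_strictly_increasing(self):
        img = np.full((128, 128), 0.5)  # uniform: g = 1, region = 0
        phi0 = LevelSetField(circle_sdf((128, 128), (64, 64), 12.0))
        params = SnakeParams(balloon_weight=0.5, curvature_weight=0.0,
                             area_tol=1e-6, max_iters=100)
        _, trace = evolve(img, phi0, params)
        assert np.all(np.diff(trace.areas) > 0)

    def test_evolution_is_deterministic(self):
        rng = np.random.default_rng(2)
        img = np.clip(rng.normal(0.5, 0.1, (96, 96)), 0, 1)
        phi0 = LevelSetField(circle_sdf((96, 96), (48, 48), 15.0))
        params = SnakeParams(max_iters=40)
        f1, t1 = evolve(img, phi0, params)
        f2, t2 = evolve(img, phi0, params)
        np.testing.assert_array_equal(f1.phi, f2.phi)
        assert t1.areas == t2.areas
        assert t1.stop_reason == t2.stop_reason

    def test_stop_reason_area_converged_when_rule_fires_before_cap(self):
        yy, xx = np.mgrid[0:128, 0:128]
        r = np.hypot(yy - 64, xx - 64)
        img = np.full((128, 128), 0.8)
        img[(r >= 40) & (r <= 44)] = 0.2
        phi0 = LevelSetField(signed_distance(r <= 25))
        _, trace = evolve(img, phi0, SnakeParams(balloon_weight=0.3, max_iters=500))
        assert trace.stop_reason == "area_converged"
        assert trace.n_iters < 500
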