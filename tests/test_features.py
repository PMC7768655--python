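import numpy as np
import pytest

import phconnectome as ph
from phconnectome.features import DEFAULT_GRID, landscape_feature_vector
from phconnectome.topology import Barcode

from _oracles import brute_force_landscape


def _b0(bars):
    return Barcode(0, np.asarray(bars, dtype=float))


def _b1(bars):
    return Barcode(1, np.asarray(bars, dtype=float))


class TestBeta0Step:
    def test_constant_when_no_merges(self):
        step = ph.beta0_step_function(_b0([[0, 1.0]] * 5))
        np.testing.assert_array_equal(step, 5.0)

    def test_drop_at_merge_threshold(self):
        bars = [[0, 0.4]] * 3 + [[0, 1.0]] * 3  # 6 components -> 3 after 0.4
        step = ph.beta0_step_function(_b0(bars))
        grid = DEFAULT_GRID
        assert step[grid < 0.4][-1] == 6
        assert step[grid > 0.4][0] == 3

    def test_single_node(self):
        np.testing.assert_array_equal(ph.beta0_step_function(_b0([[0, 1.0]])), 1.0)

    def test_dimension_check(self):
        with pytest.raises(ph.ParameterError):
            ph.beta0_step_function(_b1(np.empty((0, 2))))


class TestFdaSmooth:
    def test_affine_data_reproduced_without_penalty(self):
        y = 3.0 - 2.0 * DEFAULT_GRID
        curve = ph.fda_smooth(y, smoothing_lambda=0.0)
        np.testing.assert_allclose(curve.values, y, atol=1e-8)

    def test_derivative_of_affine_fit_constant(self):
        y = 3.0 - 2.0 * DEFAULT_GRID
        curve = ph.fda_smooth(y, smoothing_lambda=0.0)
        np.testing.assert_allclose(curve.derivative, -2.0, atol=1e-6)

    def test_huge_penalty_collapses_to_line(self):
        # heavy roughness penalty drives the fit into the penalty null space
        step = ph.beta0_step_function(_b0([[0, x] for x in
                                           (0.1, 0.2, 0.4, 0.55, 0.7, 1.0)]))
        curve = ph.fda_smooth(step, smoothing_lambda=1e8)
        coef = np.polyfit(curve.grid, curve.values, 1)
        line = np.polyval(coef, curve.grid)
        assert np.abs(curve.values - line).max() < 1e-3

    def test_start_near_component_count(self):
        step = ph.beta0_step_function(_b0([[0, x] for x in
                                           (0.3, 0.5, 0.6, 0.8, 1.0)]))
        curve = ph.fda_smooth(step)
        assert curve.values[0] == pytest.approx(5.0, abs=0.2)


class TestCurveDistance:
    def _curves(self):
        y1 = ph.beta0_step_function(_b0([[0, 0.3], [0, 0.7], [0, 1.0]]))
        y2 = ph.beta0_step_function(_b0([[0, 0.5], [0, 0.6], [0, 1.0]]))
        return ph.fda_smooth(y1), ph.fda_smooth(y2)

    def test_identical_zero_all_metrics(self):
        c1, _ = self._curves()
        for metric in ("cityblock", "euclidean"):
            assert ph.curve_distance(c1, c1, metric) == 0.0
        v = np.ones_like(c1.grid)
        assert ph.curve_distance(c1, c1, "seuclidean", variance=v) == 0.0

    def test_symmetry(self):
        c1, c2 = self._curves()
        assert ph.curve_distance(c1, c2) == pytest.approx(
            ph.curve_distance(c2, c1)
        )

    def test_cityblock_on_known_vectors(self):
        from scipy.spatial.distance import cityblock

        assert cityblock([0, 0], [1, 1]) == 2

    def test_grid_mismatch_rejected(self):
        c1, _ = self._curves()
        short = ph.fda_smooth(np.ones(100), grid=np.linspace(0, 1, 100))
        with pytest.raises(ph.ParameterError):
            ph.curve_distance(c1, short)


class TestLandscape:
    def test_single_bar_tent(self):
        land = ph.landscape(_b1([[0.0, 1.0]]))
        assert land(0.5, 0)[0] == pytest.approx(0.5)
        assert land(0.5, 1)[0] == 0.0
        assert land.n_layers == 1

    def test_two_overlapping_bars_layer_crossing(self):
        land = ph.landscape(np.array([[0.0, 2.0], [1.0, 3.0]]))
        assert land(1.5, 0)[0] == pytest.approx(0.5)
        assert land(1.5, 1)[0] == pytest.approx(0.5)

    def test_empty_barcode(self):
        land = ph.landscape(_b1(np.empty((0, 2))))
        assert land.n_layers == 0
        np.testing.assert_array_equal(land(np.linspace(0, 1, 5)), 0.0)

    def test_matches_brute_force_on_random_barcodes(self, rng):
        xs = np.linspace(0.0, 1.0, 777)
        for _ in range(25):
            n = rng.integers(1, 9)
            births = rng.uniform(0, 0.8, n)
            deaths = births + rng.uniform(0.01, 1.0 - births)
            bars = np.column_stack([births, deaths])
            land = ph.landscape(bars)
            for k in range(1, n + 1):
                np.testing.assert_allclose(
                    land(xs, k - 1), brute_force_landscape(bars, k, xs),
                    atol=1e-9,
                )

    def test_layers_pointwise_ordered(self, rng):
        bars = np.column_stack([rng.uniform(0, 0.5, 6),
                                rng.uniform(0.5, 1.0, 6)])
        land = ph.landscape(bars)
        xs = np.linspace(0, 1, 200)
        for k in range(land.n_layers - 1):
            assert np.all(land(xs, k) >= land(xs, k + 1) - 1e-12)


class TestMeanLandscape:
    def test_identity(self):
        land = ph.landscape(np.array([[0.1, 0.9]]))
        mean = ph.mean_landscape([land, land])
        xs = np.linspace(0, 1, 101)
        np.testing.assert_allclose(mean(xs, 0), land(xs, 0), atol=1e-12)

    def test_mean_with_zero_halves(self):
        land = ph.landscape(np.array([[0.1, 0.9]]))
        zero = ph.Landscape(layers=[])
        mean = ph.mean_landscape([land, zero])
        xs = np.linspace(0, 1, 101)
        np.testing.assert_allclose(mean(xs, 0), land(xs, 0) / 2, atol=1e-12)

    def test_pointwise_average_oracle(self, rng):
        lands = [
            ph.landscape(np.column_stack([rng.uniform(0, 0.4, 4),
                                          rng.uniform(0.5, 1.0, 4)]))
            for _ in range(3)
        ]
        mean = ph.mean_landscape(lands)
        xs = np.linspace(0, 1, 333)
        for k in range(mean.n_layers):
            direct = np.mean([l(xs, k) for l in lands], axis=0)
            np.testing.assert_allclose(mean(xs, k), direct, atol=1e-12)


class TestLandscapeDistance:
    def test_identical_zero(self):
        land = ph.landscape(np.array([[0.1, 0.7], [0.2, 0.9]]))
        assert ph.landscape_distance(land, land, 2) == 0.0

    def test_disjoint_tents_sup_norm(self):
        l1 = ph.landscape(np.array([[0.0, 1.0]]))
        l2 = ph.landscape(np.array([[1.0, 2.0]]))
        assert ph.landscape_distance(l1, l2, np.inf) == pytest.approx(0.5)

    def test_matches_numeric_integration(self, rng):
        xs = np.linspace(-0.5, 1.5, 200_001)
        for _ in range(5):
            l1 = ph.landscape(np.column_stack([rng.uniform(0, 0.4, 3),
                                               rng.uniform(0.5, 1.0, 3)]))
            l2 = ph.landscape(np.column_stack([rng.uniform(0, 0.4, 3),
                                               rng.uniform(0.5, 1.0, 3)]))
            for p in (1.0, 2.0, 3.0):
                num = 0.0
                for k in range(max(l1.n_layers, l2.n_layers)):
                    num += np.trapezoid(np.abs(l1(xs, k) - l2(xs, k)) ** p, xs)
                assert ph.landscape_distance(l1, l2, p) == pytest.approx(
                    num ** (1 / p), abs=1e-4
                )

    def test_triangle_inequality(self, rng):
        lands = [
            ph.landscape(np.column_stack([rng.uniform(0, 0.4, 3),
                                          rng.uniform(0.5, 1.0, 3)]))
            for _ in range(3)
        ]
        for p in (1.0, 2.0, np.inf):
            d01 = ph.landscape_distance(lands[0], lands[1], p)
            d12 = ph.landscape_distance(lands[1], lands[2], p)
            d02 = ph.landscape_distance(lands[0], lands[2], p)
            assert d02 <= d01 + d12 + 1e-10

    def test_stability_under_endpoint_perturbation(self, rng):
        # sup-norm landscape distance is 1-Lipschitz in barcode perturbation
        bars = np.column_stack([rng.uniform(0, 0.4, 5), rng.uniform(0.5, 1.0, 5)])
        for delta in (0.01, 0.05):
            noise = rng.uniform(-delta, delta, bars.shape)
            l1 = ph.landscape(bars)
            l2 = ph.landscape(bars + noise)
            assert ph.landscape_distance(l1, l2, np.inf) <= delta + 1e-12

    def test_invalid_p(self):
        land = ph.landscape(np.array([[0.1, 0.7]]))
        with pytest.raises(ph.ParameterError):
            ph.landscape_distance(land, land, 0.5)


def test_feature_vector_length():
    land = ph.landscape(np.array([[0.1, 0.7]]))
    assert landscape_feature_vector(land, n_layers=5, n_points=200).shape == (1000,)
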