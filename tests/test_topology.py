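import numpy as np
import pytest

import phconnectome as ph
from phconnectome.topology import _sorted_edges

from _oracles import betti_numbers_at, single_linkage_merge_heights


def _dist_from_edges(m, edges, default=1.0):
    d = np.full((m, m), default)
    np.fill_diagonal(d, 0.0)
    for i, j, w in edges:
        d[i, j] = d[j, i] = w
    return d


class TestBeta0:
    def test_six_nodes_six_bars_at_zero(self, random_distance):
        d = random_distance(6)
        bc = ph.beta0_barcode(d)
        assert len(bc.bars) == 6
        assert np.all(bc.bars[:, 0] == 0)
        assert np.all(bc.bars[:, 1] > 0)  # all six alive at filtration 0

    def test_path_graph_merge_heights(self):
        d = _dist_from_edges(3, [(0, 1, 0.2), (1, 2, 0.5), (0, 2, 0.9)])
        bc = ph.beta0_barcode(d)
        np.testing.assert_allclose(np.sort(bc.bars[:, 1]), [0.2, 0.5, 1.0])

    def test_complete_equal_weights_simultaneous_merge(self):
        m, w = 5, 0.4
        d = np.full((m, m), w)
        np.fill_diagonal(d, 0.0)
        bc = ph.beta0_barcode(d)
        deaths = np.sort(bc.bars[:, 1])
        np.testing.assert_allclose(deaths[:-1], w)
        assert deaths[-1] == 1.0

    def test_matches_single_linkage_on_random_instances(self, random_distance):
        for m in (6, 9, 12):
            for _ in range(34):
                d = random_distance(m)
                bc = ph.beta0_barcode(d)
                finite = np.sort(bc.bars[:, 1])[:-1]  # one essential bar
                np.testing.assert_allclose(
                    finite, single_linkage_merge_heights(d), atol=1e-12
                )

    def test_disconnected_components_capped(self):
        d = _dist_from_edges(4, [(0, 1, 0.3), (2, 3, 0.4)])
        bc = ph.beta0_barcode(d)
        assert np.sum(bc.bars[:, 1] == 1.0) == 2


class TestBeta1:
    def test_triangle_fills_at_birth(self):
        d = np.full((3, 3), 0.5)
        np.fill_diagonal(d, 0.0)
        bc, cycles = ph.beta1_barcode(d)
        assert len(bc.bars) == 0
        assert cycles == []

    def test_square_with_late_diagonals(self):
        edges = [(0, 1, 0.3), (1, 2, 0.3), (2, 3, 0.3), (0, 3, 0.3),
                 (0, 2, 0.9), (1, 3, 0.9)]
        d = _dist_from_edges(4, edges)
        bc, cycles = ph.beta1_barcode(d)
        assert len(bc.bars) == 1
        np.testing.assert_allclose(bc.bars[0], [0.3, 0.9])
        assert cycles[0].edge_set == {(0, 1), (1, 2), (2, 3), (0, 3)}

    def test_two_disjoint_squares(self):
        edges = [(0, 1, 0.2), (1, 2, 0.2), (2, 3, 0.2), (0, 3, 0.2),
                 (4, 5, 0.4), (5, 6, 0.4), (6, 7, 0.4), (4, 7, 0.4)]
        d = _dist_from_edges(8, edges)
        bc, cycles = ph.beta1_barcode(d)
        assert len(bc.bars) == 2
        sets = [c.edge_set for c in cycles]
        assert sets[0].isdisjoint(sets[1])

    def test_never_filled_cycle_capped_at_one(self):
        edges = [(0, 1, 0.2), (1, 2, 0.3), (2, 3, 0.4), (0, 3, 0.5)]
        d = _dist_from_edges(4, edges)  # diagonals absent (d = 1)
        bc, _ = ph.beta1_barcode(d)
        assert len(bc.bars) == 1
        assert bc.bars[0, 1] == 1.0

    def test_bars_match_betti_curve_oracle(self, random_distance):
        # independent check via GF(2) boundary ranks at event midpoints
        for m in (8, 10, 12):
            for _ in range(5):
                d = random_distance(m)
                bc, _ = ph.beta1_barcode(d)
                events = np.unique(np.r_[[w for w, _, _ in _sorted_edges(d)], 1.0])
                mids = (events[:-1] + events[1:]) / 2
                for eps in mids[:: max(1, len(mids) // 8)]:
                    alive = np.sum(
                        (bc.bars[:, 0] < eps) & (eps < bc.bars[:, 1])
                    )
                    _, beta1 = betti_numbers_at(d, eps)
                    assert alive == beta1

    def test_representative_is_closed_cycle(self, random_distance):
        d = random_distance(10)
        _, cycles = ph.beta1_barcode(d)
        for c in cycles:
            degree: dict[int, int] = {}
            for i, j in c.edge_set:
                degree[i] = degree.get(i, 0) + 1
                degree[j] = degree.get(j, 0) + 1
            assert all(v == 2 for v in degree.values())
            assert c.persistence >= 0

    def test_relabeling_preserves_barcode(self, rng, random_distance):
        d = random_distance(9)
        perm = rng.permutation(9)
        dp = d[np.ix_(perm, perm)]
        bc, _ = ph.beta1_barcode(d)
        bcp, _ = ph.beta1_barcode(dp)
        a = sorted(map(tuple, bc.bars))
        b = sorted(map(tuple, bcp.bars))
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestEulerConsistency:
    def test_beta0_alive_equals_component_count(self, random_distance):
        from phconnectome.topology import components_at

        for _ in range(20):
            d = random_distance(10)
            bc = ph.beta0_barcode(d)
            events = np.unique(np.r_[0.0, [w for w, _, _ in _sorted_edges(d)], 1.0])
            mids = (events[:-1] + events[1:]) / 2
            for eps in mids:
                alive = np.sum(
                    (bc.bars[:, 0] <= eps)
                    & ((eps < bc.bars[:, 1]) | (bc.bars[:, 1] >= 1.0))
                )
                assert alive == components_at(d, eps)


class TestFrequencyNetwork:
    def _cycle(self, nodes, birth, death):
        return ph.CycleRecord(birth, death, tuple(nodes))

    def test_single_cycle_unit_frequencies(self):
        f = ph.frequency_network([self._cycle([0, 1, 2, 3], 0.1, 0.9)], 5,
                                 min_persistence=0.0)
        assert f[0, 1] == 1.0 and f[2, 3] == 1.0
        assert f[0, 2] == 0.0

    def test_probability_ratio(self):
        cycles = [
            self._cycle([0, 1, 2, 3], 0.1, 0.9),
            self._cycle([0, 1, 4, 5], 0.1, 0.9),
            self._cycle([2, 3, 4, 5], 0.1, 0.9),
            self._cycle([1, 2, 4, 5], 0.1, 0.9),
        ]
        f = ph.frequency_network(cycles, 6, min_persistence=0.0)
        assert f[0, 1] == pytest.approx(0.5)  # edge (0,1) in 2 of 4 cycles

    def test_empty_cycles_zero_matrix(self):
        np.testing.assert_array_equal(ph.frequency_network([], 4), 0.0)

    def test_median_persistence_default_retains_half(self):
        cycles = [
            self._cycle([0, 1, 2], 0.1, 0.2),   # persistence 0.1
            self._cycle([3, 4, 5], 0.1, 0.8),   # persistence 0.7
        ]
        f = ph.frequency_network(cycles, 6)
        assert f[3, 4] == 1.0
        assert f[0, 1] == 0.0

    def test_persistence_weighted_mode(self):
        cycles = [
            self._cycle([0, 1, 2], 0.0, 0.2),   # persistence 0.2
            self._cycle([0, 1, 3], 0.0, 0.6),   # persistence 0.6
        ]
        f = ph.frequency_network(cycles, 4, mode="persistence_weighted",
                                 min_persistence=0.0)
        assert f[0, 1] == pytest.approx(1.0)
        assert f[1, 2] == pytest.approx(0.25)
        assert f[1, 3] == pytest.approx(0.75)
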