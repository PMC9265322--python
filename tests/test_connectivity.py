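import math

import numpy as np
import pandas as pd
import pytest

from econetkit.connectivity import (PatchGraph, compute_iic, compute_lcp,
                                    compute_pc, importance,
                                    max_product_probability, n_components,
                                    patch_distances, select_sources,
                                    threshold_sweep)
from econetkit.mspa import CorePatch

from oracles import enumerate_max_product, enumerate_nl


def _patch(pid, cells, cell_size=30.0):
    cells = tuple(cells)
    n = len(cells)
    return CorePatch(id=pid, cells=cells, area_cells=n,
                     area_km2=n * cell_size ** 2 / 1e6,
                     centroid=(float(np.mean([c[0] for c in cells])),
                               float(np.mean([c[1] for c in cells]))))


def _graph(areas, d, threshold, prob=0.5, sl=None):
    return PatchGraph(areas=np.asarray(areas, float), distances=np.asarray(d, float),
                      threshold=threshold, probability_at_threshold=prob,
                      total_area=sl)


class TestPatchDistances:
    def test_adjacent_patches_are_zero_meters(self):
        a = _patch(1, [(0, 0), (0, 1)])
        b = _patch(2, [(0, 2)])
        d = patch_distances([a, b], 30.0)
        assert d[0, 1] == 0.0

    def test_row_separation_hand_geometry(self):
        # nearest cells 10 cells apart on a row -> (10 - 1) x 30 = 270 m
        a = _patch(1, [(5, 0)])
        b = _patch(2, [(5, 10)])
        d = patch_distances([a, b], 30.0)
        assert d[0, 1] == pytest.approx(270.0)

    def test_single_patch_zero_matrix(self):
        d = patch_distances([_patch(1, [(0, 0)])], 30.0)
        assert d.shape == (1, 1) and d[0, 0] == 0.0


class TestClosedForms:
    def test_lcp_single_component_is_one(self):
        g = _graph([3.0, 1.0], [[0, 10], [10, 0]], threshold=100)
        assert compute_lcp(g) == pytest.approx(1.0, abs=1e-12)

    def test_lcp_two_components(self):
        g = _graph([3.0, 1.0], [[0, 500], [500, 0]], threshold=100)
        assert compute_lcp(g) == pytest.approx(0.625, abs=1e-12)

    def test_splitting_a_component_decreases_lcp(self):
        connected = _graph([2.0, 2.0], [[0, 50], [50, 0]], threshold=100)
        split = _graph([2.0, 2.0], [[0, 500], [500, 0]], threshold=100)
        assert compute_lcp(split) < compute_lcp(connected)

    def test_iic_single_patch_is_one(self):
        g = _graph([4.0], [[0.0]], threshold=100)
        assert compute_iic(g) == pytest.approx(1.0, abs=1e-12)

    def test_iic_two_connected_unit_patches(self):
        g = _graph([1.0, 1.0], [[0, 50], [50, 0]], threshold=100)
        assert compute_iic(g) == pytest.approx(0.75, abs=1e-12)

    def test_iic_two_disconnected_unit_patches(self):
        g = _graph([1.0, 1.0], [[0, 500], [500, 0]], threshold=100)
        assert compute_iic(g) == pytest.approx(0.5, abs=1e-12)

    def test_pc_single_patch_is_one(self):
        g = _graph([4.0], [[0.0]], threshold=100)
        assert compute_pc(g) == pytest.approx(1.0, abs=1e-12)

    def test_pc_two_patches_at_threshold_distance(self):
        # p = 0.5 exactly at the threshold by kernel calibration
        g = _graph([1.0, 1.0], [[0, 1000], [1000, 0]], threshold=1000)
        assert compute_pc(g) == pytest.approx(0.75, abs=1e-12)

    def test_pc_two_hop_beats_direct_when_probabilities_compound(self):
        # collinear at 0, 600, 1200 m; threshold 1000: direct 0-2 edge absent,
        # best path is the two-hop product
        d = [[0, 600, 1200], [600, 0, 600], [1200, 600, 0]]
        g = _graph([1.0, 1.0, 1.0], d, threshold=1000)
        mu = max_product_probability(g)
        p600 = 0.5 ** (600 / 1000)
        assert mu[0, 2] == pytest.approx(p600 ** 2, abs=1e-12)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(6))
    def test_shortest_links_and_max_product_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        pts = rng.uniform(0, 3000, size=(n, 2))
        d = np.hypot(*(pts[:, None, :] - pts[None, :, :]).transpose(2, 0, 1))
        np.fill_diagonal(d, 0.0)
        d = (d + d.T) / 2
        thr = 1000.0
        g = _graph(rng.uniform(0.5, 5, n), d, threshold=thr)
        adj = g.adjacency().tolist()
        k = math.log(0.5) / thr
        prob = np.exp(k * d).tolist()
        mu = max_product_probability(g)
        from econetkit.connectivity import _nl_matrix
        nl = _nl_matrix(g)
        for i in range(n):
            for j in range(n):
                assert mu[i, j] == pytest.approx(
                    enumerate_max_product(prob, adj, i, j), abs=1e-10)
                want_nl = enumerate_nl(adj, i, j)
                got = nl[i, j]
                assert (math.isinf(got) and math.isinf(want_nl)) or got == want_nl


class TestImportance:
    def test_isolated_patch_removal_matches_hand_computation(self):
        # 3 patches: 1-2 connected, 3 isolated; IIC numerator by hand
        d = [[0, 100, 5000], [100, 0, 5000], [5000, 5000, 0]]
        areas = [2.0, 1.0, 3.0]
        g = _graph(areas, d, threshold=500)
        sl = 6.0
        num_full = 4 + 1 + 9 + 2 * (2 * 1 / 2)  # a1^2+a2^2+a3^2 + 2 a1 a2/(1+1)
        iic_full = num_full / sl ** 2
        # removing patch 3 (SL fixed): numerator loses 9
        diic3 = 100 * (num_full - (num_full - 9)) / num_full
        table = importance(g, "IIC")
        assert compute_iic(g) == pytest.approx(iic_full, abs=1e-12)
        assert table["dIIC"].iloc[2] == pytest.approx(diic3, abs=1e-9)

    def test_duplicate_geometry_patches_have_equal_importance(self):
        d = [[0, 200, 800], [200, 0, 800], [800, 800, 0]]
        g = _graph([2.0, 2.0, 5.0], d, threshold=500)
        t = importance(g, "PC")
        assert t["dPC"].iloc[0] == pytest.approx(t["dPC"].iloc[1], abs=1e-12)

    def test_importance_requires_two_patches(self):
        with pytest.raises(ValueError):
            importance(_graph([1.0], [[0.0]], threshold=100), "PC")


class TestSweepAndSelection:
    def _patches(self):
        rng = np.random.default_rng(2)
        patches = []
        for pid in range(1, 7):
            r0, c0 = rng.integers(0, 60, 2)
            size = int(rng.integers(2, 5))
            cells = [(r0 + i, c0 + j) for i in range(size) for j in range(size)]
            patches.append(_patch(pid, cells, cell_size=100.0))
        return patches

    def test_iic_pc_nondecreasing_in_threshold(self):
        table = threshold_sweep(self._patches(), 100.0,
                                [100, 500, 1000, 1500, 2000])
        assert len(table) == 5
        assert (np.diff(table["IIC"]) >= -1e-12).all()
        assert (np.diff(table["PC"]) >= -1e-12).all()

    def test_subthreshold_distances_leave_all_components_isolated(self):
        a = _patch(1, [(0, 0)])
        b = _patch(2, [(0, 50)])
        table = threshold_sweep([a, b], 100.0, [10, 20])
        assert (table["NC"] == 2).all()
        assert table["PC"].iloc[0] == table["PC"].iloc[1]

    def test_select_sources_strict_threshold(self):
        imp = pd.DataFrame({"patch_id": [1, 2, 3], "dPC": [2.3, 1.0, 0.4]})
        assert select_sources(imp, 1.0) == [1]

    def test_select_sources_empty_when_all_below(self):
        imp = pd.DataFrame({"patch_id": [1, 2], "dPC": [0.2, 0.9]})
        assert select_sources(imp, 1.0) == []


def test_adding_a_patch_never_decreases_pc_numerator():
    d2 = np.array([[0.0, 400.0], [400.0, 0.0]])
    g2 = _graph([2.0, 3.0], d2, threshold=1000)
    num2 = compute_pc(g2) * g2.sl ** 2
    d3 = np.array([[0, 400, 2500], [400, 0, 2500], [2500, 2500, 0]], float)
    g3 = _graph([2.0, 3.0, 1.0], d3, threshold=1000)
    num3 = compute_pc(g3) * g3.sl ** 2
    assert num3 >= num2 - 1e-12


def test_iic_equals_pc_in_binary_adjacency_limit():
    """With p -> 1 on every edge, best-path products approach 1 wherever a path
    exists, matching IIC's component structure in the nl -> 0 limit."""
    d = np.array([[0, 100, 5000], [100, 0, 5000], [5000, 5000, 0]], float)
    g = _graph([1.0, 2.0, 4.0], d, threshold=500, prob=1 - 1e-12)
    mu = max_product_probability(g)
    adj_reach = np.array([[1, 1, 0], [1, 1, 0], [0, 0, 1]], float)
    np.testing.assert_allclose(mu, adj_reach, atol=1e-9)
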