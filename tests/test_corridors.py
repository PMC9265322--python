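import math

import numpy as np
import pytest

from econetkit.corridors import (CostPath, assign_level, classify_corridors,
                                 cost_distance, gravity, least_cost_paths)
from econetkit.grid import Grid
from econetkit.mspa import CorePatch

from oracles import relaxation_cost_distance


def _patch(pid, cells, cell_size=1000.0):
    cells = tuple(cells)
    return CorePatch(id=pid, cells=cells, area_cells=len(cells),
                     area_km2=len(cells) * cell_size ** 2 / 1e6,
                     centroid=(0.0, 0.0))


class TestCostDistance:
    def test_uniform_surface_unit_metric(self):
        surf = Grid(np.ones((5, 5)), cell_size=30.0)
        cf = cost_distance(surf, [(2, 2)])
        cost = cf.cumulative_cost.values
        assert cost[2, 2] == 0.0
        assert cost[2, 3] == pytest.approx(1.0)
        assert cost[1, 1] == pytest.approx(math.sqrt(2))
        assert cost[0, 0] == pytest.approx(2 * math.sqrt(2))

    def test_high_cost_wall_forces_detour(self):
        theta = np.ones((5, 5))
        theta[0:4, 2] = 100.0  # wall with a gap at the bottom
        surf = Grid(theta, cell_size=30.0)
        cost = cost_distance(surf, [(0, 0)]).cumulative_cost.values
        want = relaxation_cost_distance(theta.tolist(), [(0, 0)])
        np.testing.assert_allclose(cost, np.asarray(want), atol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_relaxation_oracle_on_random_grids(self, seed):
        rng = np.random.default_rng(seed)
        shape = (int(rng.integers(3, 7)), int(rng.integers(3, 7)))
        theta = rng.uniform(0.5, 20.0, shape)
        src = (int(rng.integers(shape[0])), int(rng.integers(shape[1])))
        cost = cost_distance(Grid(theta), [src]).cumulative_cost.values
        want = relaxation_cost_distance(theta.tolist(), [src])
        np.testing.assert_allclose(cost, np.asarray(want), atol=1e-9)

    def test_multi_source_is_pointwise_minimum(self):
        rng = np.random.default_rng(1)
        theta = rng.uniform(1, 10, (6, 6))
        surf = Grid(theta)
        a = cost_distance(surf, [(0, 0)]).cumulative_cost.values
        b = cost_distance(surf, [(5, 5)]).cumulative_cost.values
        both = cost_distance(surf, [(0, 0), (5, 5)]).cumulative_cost.values
        np.testing.assert_allclose(both, np.minimum(a, b), atol=1e-9)

    def test_nonpositive_resistance_rejected(self):
        with pytest.raises(ValueError, match="> 0"):
            cost_distance(Grid(np.zeros((3, 3))), [(0, 0)])


class TestLeastCostPaths:
    def test_straight_path_on_uniform_surface(self):
        surf = Grid(np.ones((5, 30)), cell_size=1000.0)
        a = _patch(1, [(2, 0)])
        b = _patch(2, [(2, 29)])
        paths = least_cost_paths(surf, [a, b], min_length_km=10.0)
        assert len(paths) == 1
        p = paths[0]
        assert p.cum_cost == pytest.approx(29.0)  # theta=1 x 29 unit steps
        assert p.length_km == pytest.approx(29.0)
        assert p.cells[0] == (2, 0) and p.cells[-1] == (2, 29)

    def test_backtraced_cost_equals_field_value(self):
        rng = np.random.default_rng(4)
        theta = rng.uniform(1, 30, (20, 25))
        surf = Grid(theta, cell_size=1000.0)
        a = _patch(1, [(1, 1), (1, 2)])
        b = _patch(2, [(18, 22)])
        paths = least_cost_paths(surf, [a, b], min_length_km=0.0)
        p = paths[0]
        # recompute the path's cost from per-step move costs
        total = 0.0
        for (r0, c0), (r1, c1) in zip(p.cells, p.cells[1:]):
            step = math.sqrt(2) if (r0 != r1 and c0 != c1) else 1.0
            total += 0.5 * (theta[r0, c0] + theta[r1, c1]) * step
        assert total == pytest.approx(p.cum_cost, abs=1e-9)

    def test_short_paths_filtered(self):
        surf = Grid(np.ones((5, 8)), cell_size=30.0)  # max span ~0.25 km
        a = _patch(1, [(2, 0)])
        b = _patch(2, [(2, 7)])
        assert least_cost_paths(surf, [a, b], min_length_km=10.0) == []

    def test_collinear_patch_duplicates_removed(self):
        surf = Grid(np.ones((3, 40)), cell_size=1000.0)
        a = _patch(1, [(1, 0)])
        b = _patch(2, [(1, 20)])
        c = _patch(3, [(1, 39)])
        paths = least_cost_paths(surf, [a, b, c], min_length_km=0.0,
                                 dedup_overlap=0.9)
        pairs = {(p.src_id, p.dst_id) for p in paths}
        # the 1-3 path contains both sub-paths; subset pairs are deduplicated
        assert len(paths) == 2
        assert (1, 2) in pairs and (2, 3) in pairs


class TestGravity:
    def test_closed_form_at_lmax_with_area_e(self):
        # single pair: L = L_max, both areas e hectares -> G = 1
        e_ha_km2 = math.e / 100.0
        p = CostPath(1, 2, [(0, 0), (0, 1)], length_km=5.0, cum_cost=50.0)
        g = gravity([p], {1: e_ha_km2, 2: e_ha_km2}, area_unit="ha")
        assert g["gravity"].iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_halving_resistance_quadruples_gravity(self):
        p1 = CostPath(1, 2, [(0, 0)], 5.0, cum_cost=100.0)
        p2 = CostPath(1, 3, [(0, 0)], 5.0, cum_cost=50.0)
        areas = {1: 1.0, 2: 1.0, 3: 1.0}
        g = gravity([p1, p2], areas).set_index("dst")["gravity"]
        assert g[3] == pytest.approx(4 * g[2])

    def test_three_patch_matrix_matches_hand_arithmetic(self):
        areas = {1: 2.0, 2: 5.0, 3: 1.0}  # km2 -> 200/500/100 ha
        paths = [CostPath(1, 2, [(0, 0)], 5.0, 80.0),
                 CostPath(1, 3, [(0, 0)], 5.0, 40.0),
                 CostPath(2, 3, [(0, 0)], 5.0, 100.0)]
        g = gravity(paths, areas)
        lmax = 100.0
        want12 = lmax ** 2 * math.log(200) * math.log(500) / 80.0 ** 2
        got12 = g[(g.src == 1) & (g.dst == 2)]["gravity"].iloc[0]
        assert got12 == pytest.approx(want12, abs=1e-9)

    def test_surface_scaling_leaves_gravity_invariant(self):
        areas = {1: 2.0, 2: 5.0}
        p = [CostPath(1, 2, [(0, 0)], 5.0, 80.0)]
        p_scaled = [CostPath(1, 2, [(0, 0)], 5.0, 240.0)]
        g1 = gravity(p, areas)["gravity"].iloc[0]
        g2 = gravity(p_scaled, areas)["gravity"].iloc[0]
        assert g1 == pytest.approx(g2)

    def test_tiny_areas_rejected_with_unit_hint(self):
        p = [CostPath(1, 2, [(0, 0)], 5.0, 80.0)]
        with pytest.raises(ValueError, match="area unit"):
            gravity(p, {1: 0.005, 2: 0.005}, area_unit="ha")


class TestTiering:
    def test_published_sample_values_tier_correctly(self):
        assert assign_level(265.43) == 1
        assert assign_level(61.18) == 2
        assert assign_level(5.99) == 3
        assert assign_level(0.87) is None

    def test_boundary_exactly_100_is_level_2(self):
        assert assign_level(100.0) == 2
        assert assign_level(10.0) == 3
        assert assign_level(1.0) is None

    def test_classify_empty_input(self):
        import pandas as pd
        out = classify_corridors([], pd.DataFrame(columns=["src", "dst", "gravity"]))
        assert out.corridors == [] and out.excluded == []

    def test_classify_splits_excluded(self):
        paths = [CostPath(1, 2, [(0, 0)], 5.0, 10.0),
                 CostPath(1, 3, [(0, 0)], 5.0, 1000.0)]
        import pandas as pd
        grav = pd.DataFrame({"src": [1, 1], "dst": [2, 3],
                             "gravity": [150.0, 0.5]})
        out = classify_corridors(paths, grav)
        assert len(out.corridors) == 1 and out.corridors[0][2] == 1
        assert len(out.excluded) == 1
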