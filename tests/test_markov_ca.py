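import numpy as np
import pytest

from econetkit.grid import Grid
from econetkit.markov_ca import (CAState, TransitionMatrix, agreement,
                                 ca_allocate, default_suitability,
                                 estimate_transitions, project_demand)
from econetkit.synthetic import SynthSpec, make_series


def _raster(arr, cell_size=30.0):
    return Grid(np.asarray(arr, dtype=np.int64), cell_size=cell_size)


class TestEstimateTransitions:
    def test_identical_rasters_give_identity(self):
        rng = np.random.default_rng(0)
        a = _raster(rng.integers(1, 5, (10, 10)))
        tm = estimate_transitions(a, a)
        np.testing.assert_allclose(tm.probabilities, np.eye(len(tm.classes)))
        assert np.trace(tm.counts) == 100

    def test_constructed_fixture_counts(self):
        a = np.full((10, 10), 2)        # dry land
        b = np.full((10, 10), 2)
        b.ravel()[:7] = 7               # 7 cells convert to construction
        tm = estimate_transitions(_raster(a), _raster(b), classes=[2, 7])
        assert tm.counts[0, 1] == 7
        assert tm.counts[0, 0] == 93
        assert tm.probabilities[0, 1] == pytest.approx(0.07)

    def test_area_table_uses_cell_size(self):
        a = _raster(np.full((10, 10), 1), cell_size=1000.0)
        tm = estimate_transitions(a, a)
        assert tm.to_frame().iloc[0, 0] == pytest.approx(100.0)  # 100 km2

    def test_legend_mismatch_rejected(self):
        a = _raster([[1, 2]])
        b = _raster([[1, 9]])
        with pytest.raises(ValueError, match="legend"):
            estimate_transitions(a, b, classes=[1, 2])

    def test_parameter_recovery_from_synthetic_series(self):
        """Estimated transition probabilities recover the generating matrix
        within 3 binomial standard errors on a 200x200 landscape."""
        tm_true = np.array([[0.85, 0.10, 0.05],
                            [0.05, 0.90, 0.05],
                            [0.02, 0.08, 0.90]])
        spec = SynthSpec(shape=(200, 200), cell_size=30.0,
                         class_proportions={2: 0.4, 3: 0.35, 7: 0.25},
                         urban_radius_cells=0, river_width_cells=0,
                         n_dates=2, transition_matrix=tm_true, seed=17)
        a, b = make_series(spec)
        est = estimate_transitions(a, b, classes=[2, 3, 7])
        p = est.probabilities
        row_n = est.counts.sum(axis=1)
        for i in range(3):
            for j in range(3):
                se = np.sqrt(tm_true[i, j] * (1 - tm_true[i, j]) / row_n[i])
                assert abs(p[i, j] - tm_true[i, j]) <= 3 * se + 1e-12, (i, j)


class TestProjectDemand:
    def _tm(self, p):
        p = np.asarray(p, float)
        counts = (p * 1000).astype(np.int64)
        return TransitionMatrix(classes=list(range(1, p.shape[0] + 1)),
                                counts=counts, cell_size=30.0)

    def test_identity_matrix_preserves_counts(self):
        tm = self._tm(np.eye(3))
        assert project_demand(tm, {1: 50, 2: 30, 3: 20}) == {1: 50, 2: 30, 3: 20}

    def test_one_step_arithmetic(self):
        tm = self._tm([[0.9, 0.1], [0.0, 1.0]])
        assert project_demand(tm, {1: 100, 2: 0}, steps=1) == {1: 90, 2: 10}

    def test_two_step_matrix_power(self):
        tm = self._tm([[0.9, 0.1], [0.0, 1.0]])
        assert project_demand(tm, {1: 100, 2: 0}, steps=2) == {1: 81, 2: 19}

    def test_total_conserved_exactly_under_rounding(self):
        rng = np.random.default_rng(1)
        p = rng.dirichlet(np.ones(5), size=5)
        tm = self._tm(p)
        current = {c: int(n) for c, n in zip(tm.classes, [317, 211, 97, 53, 22])}
        out = project_demand(tm, current, steps=3)
        assert sum(out.values()) == 700


class TestCAAllocate:
    def _setup(self, shape=(40, 40), seed=0):
        rng = np.random.default_rng(seed)
        lc = rng.choice([2, 7], size=shape, p=[0.7, 0.3]).astype(np.int64)
        suit = {2: np.full(shape, 0.5), 7: np.full(shape, 0.5)}
        return Grid(lc), suit

    def test_demand_equal_to_current_is_fixed_point_on_counts(self):
        grid, suit = self._setup()
        counts = {c: int((grid.values == c).sum()) for c in (2, 7)}
        out = ca_allocate(CAState(current=grid, suitability=suit, demand=counts,
                                  seed=1))
        for c in (2, 7):
            assert (out.values == c).sum() == counts[c]

    def test_demand_shift_met_within_tolerance(self):
        grid, suit = self._setup(seed=3)
        counts = {c: int((grid.values == c).sum()) for c in (2, 7)}
        demand = {2: counts[2] - 50, 7: counts[7] + 50}
        out = ca_allocate(CAState(current=grid, suitability=suit, demand=demand,
                                  tolerance=0.005, seed=2))
        got = {c: int((out.values == c).sum()) for c in (2, 7)}
        tol = 0.005 * sum(demand.values())
        assert abs(got[7] - demand[7]) <= tol

    def test_conversions_confined_to_suitable_strip(self):
        shape = (30, 30)
        lc = np.full(shape, 2, dtype=np.int64)
        lc[:, 20:] = 7
        suit7 = np.zeros(shape)
        suit7[:, 15:20] = 1.0  # only the border strip may urbanize
        suit = {2: np.full(shape, 0.5), 7: suit7}
        counts = {2: int((lc == 2).sum()), 7: int((lc == 7).sum())}
        demand = {2: counts[2] - 50, 7: counts[7] + 50}
        out = ca_allocate(CAState(current=Grid(lc), suitability=suit,
                                  demand=demand, seed=4))
        converted = (out.values == 7) & (lc == 2)
        assert converted.sum() >= 45
        assert (np.nonzero(converted)[1] >= 15).all()

    def test_restricted_mask_frozen(self):
        grid, suit = self._setup(seed=5)
        restricted = np.zeros(grid.shape, bool)
        restricted[10:20, :] = True
        counts = {c: int((grid.values == c).sum()) for c in (2, 7)}
        demand = {2: counts[2] - 80, 7: counts[7] + 80}
        out = ca_allocate(CAState(current=grid, suitability=suit, demand=demand,
                                  restricted=restricted, seed=6))
        np.testing.assert_array_equal(out.values[10:20], grid.values[10:20])

    def test_infeasible_demand_rejected_before_iteration(self):
        grid, suit = self._setup()
        with pytest.raises(ValueError, match="infeasible"):
            ca_allocate(CAState(current=grid, suitability=suit,
                                demand={2: 10, 7: 10}))

    def test_convertibility_matrix_blocks_transitions(self):
        shape = (20, 20)
        lc = np.full(shape, 5, dtype=np.int64)   # water
        lc[:10] = 2
        conv = np.array([[True, True], [False, True]])  # rows/cols: [2, 5]
        suit = {2: np.full(shape, 0.5), 5: np.full(shape, 0.5)}
        counts = {2: 200, 5: 200}
        demand = {2: 250, 5: 150}
        out = ca_allocate(CAState(current=Grid(lc), suitability=suit,
                                  demand=demand, convertibility=conv,
                                  classes=[2, 5], seed=7))
        # water may not convert to anything: counts unchanged
        assert (out.values == 5).sum() == 200


class TestSuitability:
    def test_constant_predictor_yields_class_prior(self):
        rng = np.random.default_rng(0)
        lc = Grid(rng.choice([2, 7], size=(40, 40), p=[0.8, 0.2]))
        pred = Grid(np.full((40, 40), 3.0))
        suit = default_suitability([pred], lc, lc, sample_fraction=0.5, seed=1)
        # with no information the fitted probability is flat near the prior
        assert suit[2].std() < 1e-6
        assert suit[2].mean() == pytest.approx(0.8, abs=0.1)

    def test_separable_predictor_recovered(self):
        z = np.linspace(0, 1, 1600).reshape(40, 40)
        lc = Grid(np.where(z < 0.3, 5, 2).astype(np.int64))
        suit = default_suitability([Grid(z)], lc, lc, sample_fraction=0.5, seed=2)
        assert suit[5][z < 0.2].mean() > 0.9
        assert suit[5][z > 0.4].mean() < 0.1

    def test_per_cell_probabilities_sum_to_one(self):
        rng = np.random.default_rng(3)
        lc = Grid(rng.choice([1, 2, 7], size=(30, 30)))
        preds = [Grid(rng.normal(size=(30, 30))) for _ in range(2)]
        suit = default_suitability(preds, lc, lc, sample_fraction=0.3, seed=4)
        total = sum(suit.values())
        np.testing.assert_allclose(total, 1.0, atol=1e-9)

    def test_single_class_training_warns_uniform(self):
        lc = Grid(np.full((10, 10), 3, dtype=np.int64))
        with pytest.warns(UserWarning, match="single-class"):
            suit = default_suitability([Grid(np.ones((10, 10)))], lc, lc,
                                       classes=[3, 4], seed=5)
        np.testing.assert_allclose(suit[3], 0.5)


class TestAgreement:
    def test_identical_rasters_perfect_scores(self):
        rng = np.random.default_rng(0)
        a = _raster(rng.integers(1, 5, (20, 20)))
        kappa, oa = agreement(a, a)
        assert kappa == pytest.approx(1.0) and oa == pytest.approx(1.0)

    def test_hand_confusion_closed_form(self):
        # confusion {a=40, b=10, c=10, d=40} -> OA 0.8, kappa 0.6
        ref = np.array([1] * 50 + [2] * 50)
        sim = np.array([1] * 40 + [2] * 10 + [1] * 10 + [2] * 40)
        kappa, oa = agreement(_raster(ref.reshape(10, 10)),
                              _raster(sim.reshape(10, 10)))
        assert oa == pytest.approx(0.8)
        assert kappa == pytest.approx(0.6)

    def test_label_permutation_has_near_zero_kappa(self):
        rng = np.random.default_rng(1)
        vals = rng.integers(1, 5, size=2500)
        ref = _raster(vals.reshape(50, 50))
        sim = _raster(rng.permutation(vals).reshape(50, 50))
        kappa, _ = agreement(ref, sim)
        assert abs(kappa) < 0.05
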