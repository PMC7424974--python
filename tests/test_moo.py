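"""NSGA-II components: non-dominated sorting, crowding, the generational
loop, and ideal-point selection."""

import numpy as np
import pytest

from embryopt.moo import (
    NSGAConfig,
    crowding_distance,
    fast_nondominated_sort,
    nsga2_optimize,
    select_ideal_point,
)


def brute_force_fronts(F):
    """O(n^2 m) peeling using an explicit dominance check."""
    F = np.asarray(F, float)
    remaining = list(range(len(F)))
    fronts = []
    while remaining:
        front = []
        for i in remaining:
            dominated = False
            for j in remaining:
                if j != i and np.all(F[j] >= F[i]) and np.any(F[j] > F[i]):
                    dominated = True
                    break
            if not dominated:
                front.append(i)
        fronts.append(sorted(front))
        remaining = [i for i in remaining if i not in front]
    return fronts


class TestSorting:
    def test_three_point_example(self):
        fronts = fast_nondominated_sort(np.array([[2, 2], [0, 3], [1, 1]]))
        assert [sorted(f.tolist()) for f in fronts] == [[0, 1], [2]]

    def test_single_point(self):
        fronts = fast_nondominated_sort(np.array([[1.0, 2.0]]))
        assert len(fronts) == 1 and fronts[0].tolist() == [0]

    def test_identical_points_share_front_zero(self):
        fronts = fast_nondominated_sort(np.tile([3.0, 1.0], (5, 1)))
        assert len(fronts) == 1 and len(fronts[0]) == 5

    def test_empty_input(self):
        assert fast_nondominated_sort(np.empty((0, 2))) == []

    def test_agrees_with_brute_force_on_random_instances(self):
        rng = np.random.default_rng(77)
        for _ in range(200):
            n = int(rng.integers(1, 51))
            m = int(rng.integers(2, 4))
            F = rng.integers(0, 6, size=(n, m)).astype(float)  # ties likely
            ours = [sorted(f.tolist()) for f in fast_nondominated_sort(F)]
            assert ours == brute_force_fronts(F)


class TestCrowding:
    def test_small_fronts_are_all_boundary(self):
        assert np.all(np.isinf(crowding_distance(np.array([[1.0, 2.0]]))))
        assert np.all(
            np.isinf(crowding_distance(np.array([[1.0, 2.0], [2.0, 1.0]])))
        )

    def test_evenly_spaced_collinear_interior_value(self):
        d = crowding_distance(np.array([[0.0, 2.0], [1.0, 1.0], [2.0, 0.0]]))
        assert np.isinf(d[0]) and np.isinf(d[2])
        assert d[1] == pytest.approx(2.0)  # one normalized span per objective

    def test_permutation_invariance_of_distance_multiset(self):
        rng = np.random.default_rng(5)
        F = rng.random((12, 2))
        base = np.sort(crowding_distance(F))
        for _ in range(5):
            perm = rng.permutation(12)
            np.testing.assert_allclose(
                np.sort(crowding_distance(F[perm])), base
            )

    def test_zero_range_objective_contributes_nothing(self):
        F = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        d = crowding_distance(F)
        assert d[1] == pytest.approx(1.0)  # only the first objective counts


class TestLoop:
    def test_no_tradeoff_collapses_to_common_maximum(self):
        cfg = NSGAConfig(
            population_size=40,
            generations=60,
            bounds=((0.0, 1.0),),
            seed=1,
        )
        X, F = nsga2_optimize(lambda x: np.hstack([x, x]), cfg)
        assert np.all(X > 0.99)

    def test_total_tradeoff_front_is_mutually_nondominated(self):
        cfg = NSGAConfig(
            population_size=60, generations=80, bounds=((0.0, 1.0),), seed=2
        )
        X, F = nsga2_optimize(lambda x: np.hstack([x, 1.0 - x]), cfg)
        assert len(fast_nondominated_sort(F)) == 1
        assert X.min() < 0.1 and X.max() > 0.9  # spans the trade-off

    def test_recovers_quarter_circle_front(self):
        def objectives(X):
            norm = np.maximum(1.0, np.linalg.norm(X, axis=1, keepdims=True))
            return X / norm

        cfg = NSGAConfig(
            population_size=100,
            generations=200,
            bounds=((0.0, 1.0), (0.0, 1.0)),
            seed=3,
        )
        X, F = nsga2_optimize(objectives, cfg)
        radial_error = np.abs(np.linalg.norm(F, axis=1) - 1.0)
        assert radial_error.mean() < 0.02

    def test_elitism_keeps_per_objective_best_nondecreasing(self):
        rng_best = []

        def track(gen, X, F):
            rng_best.append(F.max(axis=0))

        def objectives(X):
            return np.stack(
                [np.sin(3 * X[:, 0]) + X[:, 1], np.cos(2 * X[:, 1]) + X[:, 0]],
                axis=1,
            )

        cfg = NSGAConfig(
            population_size=30,
            generations=50,
            bounds=((0.0, 2.0), (0.0, 2.0)),
            seed=4,
        )
        nsga2_optimize(objectives, cfg, on_generation=track)
        best = np.array(rng_best)
        assert np.all(np.diff(best, axis=0) >= -1e-12)

    def test_front_within_bounds(self):
        cfg = NSGAConfig(
            population_size=30,
            generations=30,
            bounds=((2.0, 5.0), (1.0, 3.0)),
            seed=5,
        )
        X, _ = nsga2_optimize(lambda x: x.copy(), cfg)
        assert np.all(X[:, 0] >= 2.0) and np.all(X[:, 0] <= 5.0)
        assert np.all(X[:, 1] >= 1.0) and np.all(X[:, 1] <= 3.0)

    def test_nonfinite_objective_reported_with_decision(self):
        cfg = NSGAConfig(
            population_size=10, generations=5, bounds=((0.0, 1.0),), seed=6
        )
        def bad(X):
            out = np.hstack([X, X])
            out[0, 0] = np.nan
            return out
        with pytest.raises(ValueError, match="non-finite"):
            nsga2_optimize(bad, cfg)

    def test_config_validation(self):
        with pytest.raises(ValueError, match="population"):
            NSGAConfig(population_size=5)
        with pytest.raises(ValueError, match="rates"):
            NSGAConfig(crossover_rate=1.5)
        with pytest.raises(ValueError, match="selection"):
            NSGAConfig(selection_scheme="rank")
        with pytest.raises(ValueError, match="bounds"):
            NSGAConfig(bounds=((0.0, 0.0),) * 3)

    def test_crowded_tournament_also_finds_the_front(self):
        cfg = NSGAConfig(
            population_size=40,
            generations=40,
            bounds=((0.0, 1.0),),
            seed=7,
            selection_scheme="crowded_tournament",
        )
        X, _ = nsga2_optimize(lambda x: np.hstack([x, x]), cfg)
        assert np.all(X > 0.99)


class TestIdealPoint:
    def test_front_containing_the_ideal_wins_with_zero_distance(self):
        F = np.array([[90.0, 50.0], [100.0, 57.8], [99.0, 57.0]])
        X = np.array([[1.0, 1.0, 1.0], [2.0, 2.0, 2.0], [3.0, 3.0, 3.0]])
        res = select_ideal_point(X, F, ideal=[100.0, 57.8])
        assert res.distance == pytest.approx(0.0)
        np.testing.assert_array_equal(res.selected_objectives, [100.0, 57.8])

    def test_hand_evaluated_distance(self):
        F = np.array([[99.09, 56.23]])
        X = np.array([[9.1, 4.7, 18.73]])
        res = select_ideal_point(X, F, ideal=[100.0, 57.80])
        assert res.distance == pytest.approx(
            np.sqrt(0.91**2 + 1.57**2), abs=1e-12
        )  # = 1.8146...

    def test_tie_breaks_toward_lower_first_decision(self):
        F = np.array([[99.0, 57.0], [99.0, 57.0]])
        X = np.array([[9.5, 4.7, 20.0], [9.1, 4.7, 20.0]])
        res = select_ideal_point(X, F, ideal=[100.0, 57.8])
        assert res.selected_decision[0] == 9.1

    def test_empty_front_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            select_ideal_point(np.empty((0, 3)), np.empty((0, 2)), [1.0, 1.0])


class TestEndToEndRecovery:
    def test_analytic_peak_recovered_within_half_micromolar(self):
        """With the surrogates replaced by noiseless Gaussian-peak surfaces,
        the ideal-point choice lands on the common peak."""
        from embryopt.dataset import SurfaceConfig

        surf = SurfaceConfig(
            peak_location=(9.1, 4.7, 18.7),
            widths=(4.0, 5.0, 12.0),
            noise_sd={"cal_pct": 0.0, "emb_pct": 0.0, "num": 0.0},
        )

        def objectives(X):
            return np.stack(
                [surf.response(X, "emb_pct"), surf.response(X, "num")], axis=1
            )

        cfg = NSGAConfig(population_size=100, generations=200, seed=8)
        X, F = nsga2_optimize(objectives, cfg)
        res = select_ideal_point(X, F, ideal=[100.0, 57.8])
        np.testing.assert_allclose(
            res.selected_decision, [9.1, 4.7, 18.7], atol=0.5
        )
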