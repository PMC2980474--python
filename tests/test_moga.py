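"""NSGA-II machinery: objectives, genetic operators, sorting, full loop."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mogasvm import (GAConfig, Individual, SyntheticSpec, adjusted_rand,
                     assign_points, compactness, crowding_distance, dominates,
                     evaluate_individual, generate, nondominated_sort,
                     pairwise_distances, run_moga, separation, update_centers)
from mogasvm.moga import crossover, init_population, mutate, select_parents


def brute_force_fronts(objs):
    """O(N^2) reference partition into non-dominated fronts."""
    objs = [tuple(o) for o in objs]
    remaining = list(range(len(objs)))
    fronts = []
    while remaining:
        front = [i for i in remaining
                 if not any(dominates(objs[j], objs[i])
                            for j in remaining if j != i)]
        fronts.append(sorted(front))
        remaining = [i for i in remaining if i not in front]
    return fronts


class TestObjectives:
    def test_assignment_to_nearest_center(self, tiny_1d):
        labels = assign_points(tiny_1d, np.array([[1.0], [11.0]]))
        np.testing.assert_array_equal(labels, [1, 1, 2, 2])

    def test_equidistant_point_takes_lowest_index(self):
        labels = assign_points(np.array([[5.0]]), np.array([[4.0], [6.0]]))
        assert labels[0] == 1

    def test_data_point_centers_label_to_themselves(self, rng):
        X = rng.normal(size=(10, 3))
        centers = X[[2, 5, 7]]
        labels = assign_points(X, centers)
        assert labels[2] == 1 and labels[5] == 2 and labels[7] == 3

    def test_mean_update(self):
        X = np.array([[0.0], [2.0], [10.0]])
        centers = update_centers(X, np.array([1, 1, 2]), 2)
        np.testing.assert_allclose(centers, [[1.0], [10.0]])

    def test_medoid_update_exhaustive(self):
        # cluster {0, 2, 10}: distance sums 12, 10, 18 -> medoid is 2
        X = np.array([[0.0], [2.0], [10.0]])
        centers = update_centers(X, np.array([1, 1, 1, ]), 1, mode="medoid")
        assert centers[0, 0] == 2.0

    def test_medoid_centers_are_data_rows(self, rng):
        X = rng.normal(size=(20, 4))
        labels = rng.integers(1, 4, size=20)
        for k in range(1, 4):
            if (labels == k).sum() == 0:
                labels[k] = k
        centers = update_centers(X, labels, 3, mode="medoid")
        for c in centers:
            assert any(np.array_equal(c, row) for row in X)

    def test_empty_cluster_reseeded_to_data_row(self, rng):
        X = rng.normal(size=(8, 2))
        centers = update_centers(X, np.array([1] * 8), 2, rng=rng)
        assert any(np.array_equal(centers[1], row) for row in X)

    def test_compactness_hand_value(self, tiny_1d):
        sigma = compactness(tiny_1d, np.array([1, 1, 2, 2]),
                            np.array([[1.0], [11.0]]))
        assert sigma == pytest.approx(4.0)

    def test_compactness_zero_at_centers(self):
        X = np.array([[1.0, 2.0], [5.0, 6.0]])
        assert compactness(X, np.array([1, 2]), X) == 0.0

    def test_separation_sum_and_min(self):
        centers = np.array([[0.0], [1.0], [2.0]])
        assert separation(centers, mode="sum") == pytest.approx(4.0)
        assert separation(centers, mode="min") == pytest.approx(1.0)
        two = np.array([[1.0], [11.0]])
        assert separation(two, mode="sum") == separation(two, mode="min") == 10.0

    def test_separation_translation_invariant(self, rng):
        centers = rng.normal(size=(4, 6))
        shifted = centers + rng.normal(size=6)
        for mode in ("sum", "min"):
            assert separation(centers, mode=mode) == \
                pytest.approx(separation(shifted, mode=mode))

    def test_pearson_distance_range_and_self(self, rng):
        A = rng.normal(size=(5, 20))
        D = pairwise_distances(A, A, "pearson")
        np.testing.assert_allclose(np.diag(D), 0, atol=1e-12)
        assert (D >= -1e-12).all() and (D <= 2 + 1e-12).all()


class TestEvaluate:
    def test_one_hand_iteration(self, tiny_1d):
        ind = Individual(centers=np.array([[0.0], [10.0]]))
        cfg = GAConfig(seed=0)
        evaluate_individual(tiny_1d, ind, cfg, np.random.default_rng(0))
        np.testing.assert_allclose(ind.centers, [[1.0], [11.0]])
        np.testing.assert_array_equal(ind.labels, [1, 1, 2, 2])
        assert ind.objectives[0] == pytest.approx(4.0)
        assert ind.objectives[1] == pytest.approx(0.1)  # Sep = 10

    def test_converged_configuration_is_fixed_point(self, tiny_1d):
        ind = Individual(centers=np.array([[1.0], [11.0]]))
        evaluate_individual(tiny_1d, ind, GAConfig(seed=0),
                            np.random.default_rng(0))
        np.testing.assert_allclose(ind.centers, [[1.0], [11.0]])

    def test_single_kmeans_step_never_increases_sigma(self, rng):
        # mean-mode Euclidean: reassignment then mean update cannot
        # increase the summed point-to-center distance criterion
        for _ in range(20):
            X = rng.normal(size=(30, 4))
            centers = X[rng.choice(30, size=3, replace=False)]
            labels0 = assign_points(X, centers)
            sigma0 = compactness(X, labels0, centers)
            ind = Individual(centers=centers.copy())
            evaluate_individual(X, ind, GAConfig(seed=0),
                                np.random.default_rng(0))
            assert ind.objectives[0] <= sigma0 + 1e-9

    def test_degenerate_identical_centers_get_worst_objectives(self):
        X = np.array([[0.0], [1.0]])
        ind = Individual(centers=np.array([[5.0], [5.0]]))
        # identical centers: tie-rule sends everything to center 1, the
        # empty cluster 2 is repaired; if repair lands on a distinct row the
        # objectives are finite, otherwise worst -- either way no crash and
        # labels cover both clusters
        evaluate_individual(X, ind, GAConfig(seed=0), np.random.default_rng(3))
        assert set(ind.labels) == {1, 2}


class TestSortingAndCrowding:
    def test_hand_front_partition(self):
        objs = [(1, 1), (2, 2), (1, 2), (2, 1)]
        assert nondominated_sort(objs) == [[0], [2, 3], [1]]

    def test_identical_vectors_single_front(self):
        assert nondominated_sort([(1, 1)] * 5) == [[0, 1, 2, 3, 4]]

    def test_dominated_chain_singleton_fronts(self):
        assert nondominated_sort([(1, 1), (2, 2), (3, 3)]) == [[0], [1], [2]]

    def test_matches_brute_force_on_random_sets(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 40))
            objs = rng.integers(0, 6, size=(n, 2)).astype(float)
            assert [sorted(f) for f in nondominated_sort(objs)] == \
                brute_force_fronts(objs)

    def test_crowding_hand_values(self):
        d = crowding_distance([(1, 3), (2, 2), (3, 1)])
        assert d[0] == np.inf and d[2] == np.inf
        assert d[1] == pytest.approx(2.0)

    def test_small_fronts_all_infinite(self):
        assert np.isinf(crowding_distance([(1, 2)])).all()
        assert np.isinf(crowding_distance([(1, 2), (3, 4)])).all()

    def test_zero_range_objective_contributes_zero(self):
        d = crowding_distance([(1, 5), (2, 5), (3, 5)])
        assert d[1] == pytest.approx(1.0)  # only the first objective counts

    def test_dominance_basics(self):
        assert dominates((1, 2), (2, 3))
        assert not dominates((1, 2), (1, 2))
        assert not dominates((1, 3), (2, 2)) and not dominates((2, 2), (1, 3))


class TestGeneticOperators:
    def test_initial_centers_are_distinct_data_rows(self, rng):
        X = rng.normal(size=(12, 3))
        pop = init_population(X, 4, GAConfig(seed=7))
        for ind in pop:
            rows = [tuple(c) for c in ind.centers]
            assert len(set(rows)) == 4
            for c in rows:
                assert any(np.array_equal(np.array(c), r) for r in X)

    def test_init_reproducible_under_seed(self, rng):
        X = rng.normal(size=(10, 2))
        p1 = init_population(X, 3, GAConfig(seed=5))
        p2 = init_population(X, 3, GAConfig(seed=5))
        for a, b in zip(p1, p2):
            np.testing.assert_array_equal(a.centers, b.centers)

    def test_init_rejects_k_above_n(self, rng):
        with pytest.raises(ValueError):
            init_population(rng.normal(size=(3, 2)), 4, GAConfig(seed=0))

    def test_crossover_zero_probability_copies_parents(self, rng):
        p1, p2 = rng.normal(size=(2, 3, 2))
        c1, c2 = crossover(p1, p2, 0.0, rng)
        np.testing.assert_array_equal(c1, p1)
        np.testing.assert_array_equal(c2, p2)

    def test_crossover_swaps_tails_at_cut(self):
        p1 = np.array([[1.0, 2.0], [3.0, 4.0]])
        p2 = np.array([[5.0, 6.0], [7.0, 8.0]])

        class FixedRng:
            def random(self):
                return 0.0   # always cross

            def integers(self, *a, **k):
                return 2     # cut after position 2

        c1, c2 = crossover(p1, p2, 1.0, FixedRng())
        np.testing.assert_array_equal(c1.ravel(), [1, 2, 7, 8])
        np.testing.assert_array_equal(c2.ravel(), [5, 6, 3, 4])

    def test_mutation_zero_probability_is_identity(self, rng):
        c = rng.normal(size=(3, 4))
        out = mutate(c, 0.0, 0.1, np.ones(4), rng)
        np.testing.assert_array_equal(out, c)

    def test_mutation_moves_exactly_one_center_within_bounds(self, rng):
        c = rng.normal(size=(4, 5))
        ranges = np.abs(rng.normal(size=5)) + 0.5
        out = mutate(c, 1.0, 0.1, ranges, rng)
        changed = [k for k in range(4) if not np.array_equal(out[k], c[k])]
        assert len(changed) == 1
        k = changed[0]
        assert (np.abs(out[k] - c[k]) <= 0.1 * ranges + 1e-12).all()

    def test_tournament_prefers_rank_then_crowding(self, rng):
        a = Individual(centers=np.zeros((2, 1)), rank=1, crowding=0.1)
        b = Individual(centers=np.zeros((2, 1)), rank=2, crowding=np.inf)
        c = Individual(centers=np.zeros((2, 1)), rank=1, crowding=np.inf)
        from mogasvm.moga import _crowded_better
        assert _crowded_better(a, b, rng) is a
        assert _crowded_better(a, c, rng) is c

    def test_mating_pool_reproducible_under_seed(self, rng):
        pop = [Individual(centers=np.full((2, 1), float(i)), rank=1,
                          crowding=float(i)) for i in range(6)]
        pool1 = select_parents(pop, np.random.default_rng(3))
        pool2 = select_parents(pop, np.random.default_rng(3))
        assert [id(p) for p in pool1] == [id(p) for p in pool2]


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.lists(st.tuples(st.integers(0, 8), st.integers(0, 8)),
                min_size=1, max_size=30))
def test_fronts_partition_and_respect_dominance(objs):
    fronts = nondominated_sort(np.array(objs, dtype=float))
    flat = sorted(i for f in fronts for i in f)
    assert flat == list(range(len(objs)))
    for i in fronts[0]:
        assert not any(dominates(objs[j], objs[i]) for j in range(len(objs)))


class TestRunMoga:
    def test_front_members_mutually_nondominated_and_reproducible(self):
        ds = generate(SyntheticSpec(seed=3, n_genes=40,
                                    samples_per_class=8, n_classes=3))
        cfg = GAConfig(seed=3, pop_size=20, generations=15)
        f1 = run_moga(ds.X.values, 3, cfg)
        f2 = run_moga(ds.X.values, 3, cfg)
        objs = [m.objectives for m in f1.members]
        for i, a in enumerate(objs):
            for j, b in enumerate(objs):
                if i != j:
                    assert not dominates(a, b)
        assert len(f1) == len(f2)
        for a, b in zip(f1.members, f2.members):
            np.testing.assert_array_equal(a.labels, b.labels)

    def test_recovers_planted_clusters(self):
        ds = generate(SyntheticSpec(seed=11, n_genes=50,
                                    samples_per_class=15, n_classes=4))
        front = run_moga(ds.X.values, 4, GAConfig(seed=11, generations=40))
        best = max(adjusted_rand(ds.true_labels, m.labels)
                   for m in front.members)
        assert best == pytest.approx(1.0)

    def test_min_front_sigma_non_increasing_under_elitism(self):
        ds = generate(SyntheticSpec(seed=2, n_genes=40, samples_per_class=10,
                                    n_classes=3))
        front = run_moga(ds.X.values, 3,
                         GAConfig(seed=2, pop_size=20, generations=25))
        h = front.sigma_history
        assert all(h[i + 1] <= h[i] + 1e-9 for i in range(len(h) - 1))
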