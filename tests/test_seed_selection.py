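"""FCM updates, the GA optimizer and automatic seed choice."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mammoseg.phantom import PhantomSpec, generate_phantom
from mammoseg.seed_selection import (
    Chromosome,
    GAConfig,
    fcm_fit,
    fcm_memberships,
    fcm_objective,
    fcm_update_centers,
    ga_optimize,
    label_layers,
    segmentation_cost,
    select_seed,
    trilevel_reference,
)


def textbook_fcm_step(x, centers, q):
    """Independent scalar-loop FCM update (membership then centers)."""
    K, n = len(centers), len(x)
    u = np.zeros((K, n))
    for j in range(n):
        d = [abs(x[j] - c) for c in centers]
        if min(d) == 0:
            hits = [i for i in range(K) if d[i] == 0]
            for i in hits:
                u[i, j] = 1.0 / len(hits)
            continue
        for i in range(K):
            u[i, j] = 1.0 / sum((d[i] / d[k]) ** (2.0 / (q - 1.0))
                                for k in range(K))
    c_new = [
        sum(u[i, j] ** q * x[j] for j in range(n))
        / sum(u[i, j] ** q for j in range(n))
        for i in range(K)
    ]
    return u, np.array(c_new)


class TestMemberships:
    def test_pixel_at_center_gets_full_membership(self):
        u = fcm_memberships([5.0], [5.0, 9.0])
        np.testing.assert_allclose(u[:, 0], [1.0, 0.0])

    def test_equidistant_split(self):
        u = fcm_memberships([5.0], [3.0, 7.0], q=2.0)
        np.testing.assert_allclose(u[:, 0], [0.5, 0.5])

    def test_worked_example(self):
        # x=0, centers {2, 8}, q=2: u1 = 1/(1+(2/8)^2)
        u = fcm_memberships([0.0], [2.0, 8.0], q=2.0)
        np.testing.assert_allclose(u[:, 0], [0.94118, 0.05882], atol=5e-6)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fcm_memberships([1.0], [2.0], q=1.0)
        with pytest.raises(ValueError):
            fcm_memberships([1.0], [])

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 255), min_size=1, max_size=30),
           st.lists(st.floats(0, 255), min_size=1, max_size=6),
           st.floats(1.1, 5.0))
    def test_columns_sum_to_one(self, pixels, centers, q):
        u = fcm_memberships(pixels, centers, q)
        np.testing.assert_allclose(u.sum(axis=0), 1.0, atol=1e-9)
        assert (u >= 0).all() and (u <= 1 + 1e-12).all()


class TestCenters:
    def test_crisp_memberships_give_means(self):
        x = [0.0, 2.0, 10.0, 14.0]
        u = np.array([[1, 1, 0, 0], [0, 0, 1, 1.0]])
        np.testing.assert_allclose(fcm_update_centers(x, u), [1.0, 12.0])

    def test_uniform_memberships_give_global_mean(self):
        x = [1.0, 3.0, 8.0]
        u = np.full((3, 3), 1 / 3)
        np.testing.assert_allclose(fcm_update_centers(x, u, q=3.0),
                                   [4.0, 4.0, 4.0])

    def test_hand_case(self):
        x = [0.0, 10.0]
        u = np.array([[0.9, 0.1], [0.1, 0.9]])
        c = fcm_update_centers(x, u, q=2.0)
        np.testing.assert_allclose(c[0], 0.01 * 10 / 0.82, atol=1e-9)
        assert abs(c[0] - 0.12195) < 1e-4


class TestObjective:
    def test_perfect_fit_is_zero(self):
        x = [2.0, 8.0]
        u = np.array([[1, 0], [0, 1.0]])
        assert fcm_objective(x, u, [2.0, 8.0]) == 0.0

    def test_single_term(self):
        assert fcm_objective([4.0], np.array([[1.0]]), [2.0]) == 4.0

    def test_matches_bruteforce_sum(self, rng):
        x = rng.uniform(0, 255, 12)
        centers = np.array([50.0, 180.0])
        u = fcm_memberships(x, centers)
        expected = sum(
            u[i, j] ** 2 * (x[j] - centers[i]) ** 2
            for i in range(2) for j in range(12)
        )
        np.testing.assert_allclose(fcm_objective(x, u, centers), expected,
                                   rtol=1e-12)


class TestFit:
    def test_two_group_centers(self, rng):
        x = np.concatenate([10 + rng.uniform(-1, 1, 50),
                            200 + rng.uniform(-1, 1, 50)])
        state = fcm_fit(x, K=2, rng_seed=0)
        lo, hi = sorted(state.centers)
        assert abs(lo - 10) <= 2 and abs(hi - 200) <= 2

    def test_k1_is_global_mean(self):
        x = np.array([1.0, 2.0, 6.0])
        state = fcm_fit(x, K=1, rng_seed=0)
        np.testing.assert_allclose(state.centers, [3.0], atol=1e-9)

    def test_deterministic_and_monotone(self, rng):
        x = rng.uniform(0, 255, 60)
        a = fcm_fit(x, K=3, rng_seed=7)
        b = fcm_fit(x, K=3, rng_seed=7)
        np.testing.assert_array_equal(a.centers, b.centers)
        hist = np.asarray(a.history)
        assert (np.diff(hist) <= 1e-9).all()

    def test_fixed_point_matches_textbook_oracle(self, rng):
        x = rng.uniform(0, 255, 50)
        state = fcm_fit(x, K=3, q=2.0, rng_seed=1, max_iter=200, tol=1e-12)
        u_ref, c_ref = textbook_fcm_step(x, state.centers, 2.0)
        np.testing.assert_allclose(state.memberships, u_ref, atol=1e-9)
        np.testing.assert_allclose(
            fcm_update_centers(x, state.memberships), c_ref, atol=1e-9
        )
        # converged: one more full update barely moves the centers
        np.testing.assert_allclose(c_ref, state.centers, atol=1e-3)

    def test_k_validation(self):
        with pytest.raises(ValueError):
            fcm_fit([1.0], K=0)


class TestSegmentationCost:
    def test_identical_layers_zero(self):
        layers = label_layers(np.array([[0, 1], [2, 1]]), 3)
        assert segmentation_cost(layers, layers) == 0.0

    def test_single_pixel_move_costs_two(self):
        ref = label_layers(np.array([[0, 1]]), 3)
        cand = label_layers(np.array([[0, 2]]), 3)
        assert segmentation_cost(cand, ref) == 2.0

    def test_matches_bruteforce_count(self, rng):
        a = rng.integers(0, 3, size=(8, 8))
        b = rng.integers(0, 3, size=(8, 8))
        cost = segmentation_cost(label_layers(a, 3), label_layers(b, 3))
        expected = 0
        for layer in range(3):
            for r in range(8):
                for c in range(8):
                    expected += (int(a[r, c] == layer) - int(b[r, c] == layer)) ** 2
        assert cost == expected

    def test_trilevel_reference_partitions(self, rng):
        img = rng.integers(0, 256, size=(10, 10))
        gray, white, black = trilevel_reference(img)
        np.testing.assert_array_equal(gray + white + black, np.ones((10, 10)))


class TestGA:
    def test_zero_generations_returns_initial_best(self, rng):
        x = rng.uniform(0, 255, 30)
        cfg = GAConfig(population_size=10, generations=0, rng_seed=3)
        best, history = ga_optimize(x, K=2, config=cfg)
        assert history == []
        assert np.isfinite(best.fitness)

    def test_history_non_increasing(self, rng):
        x = rng.uniform(0, 255, 40)
        cfg = GAConfig(population_size=12, generations=15, rng_seed=5)
        _, history = ga_optimize(x, K=2, config=cfg)
        assert (np.diff(history) <= 0).all()

    def test_ga_competitive_with_fcm(self, rng):
        x = np.concatenate([20 + rng.normal(0, 2, 100),
                            200 + rng.normal(0, 2, 100)])
        state = fcm_fit(x, K=2, rng_seed=0)
        cfg = GAConfig(population_size=40, generations=30, rng_seed=0)
        best, _ = ga_optimize(x, K=2, config=cfg)
        assert best.fitness <= 1.05 * state.objective

    def test_config_validation(self):
        with pytest.raises(ValueError):
            GAConfig(mutation_rate=1.5)
        with pytest.raises(ValueError):
            GAConfig(population_size=1)


class TestSelectSeed:
    def test_seed_inside_bright_disk(self, noise_free_benign):
        img, mask, _ = noise_free_benign
        best = Chromosome(genes=np.array([15.0, 110.0, 165.0]), fitness=0.0)
        seed = select_seed(img, best)
        assert mask[seed.row, seed.col] == 1

    def test_tie_breaks_to_smallest_raster_position(self):
        img = np.array([[0, 9], [9, 0]], dtype=np.uint8)
        best = Chromosome(genes=np.array([0.0, 9.0]), fitness=0.0)
        seed = select_seed(img, best)
        assert (seed.row, seed.col) == (0, 1)

    def test_k1_returns_pixel_closest_to_mean(self):
        img = np.array([[0, 4, 10]], dtype=np.uint8)
        best = Chromosome(genes=np.array([img.mean()]), fitness=0.0)
        seed = select_seed(img, best)
        assert (seed.row, seed.col) == (0, 1)

    def test_multi_mode_one_seed_per_cluster(self, noise_free_benign):
        img, _, _ = noise_free_benign
        best = Chromosome(genes=np.array([15.0, 110.0, 165.0]), fitness=0.0)
        seeds = select_seed(img, best, multi=True)
        assert len(seeds) == 3
        assert sorted(s.cluster_id for s in seeds) == [0, 1, 2]
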