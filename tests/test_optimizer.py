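"""FOO population dynamics, fitness factorization, and convergence."""

import numpy as np
import pytest

from ospreyfuse import (
    FOOConfig,
    FOOState,
    ScoreTensor,
    WeightVector,
    evaluate_fitness,
    foo_step,
    fuse_batch,
    grid_search_oracle,
    optimize,
    precompute_transform_sums,
    preset_scenario,
    generate_scenario,
    transform_exponential,
    transform_sigmoid,
    transform_tanh,
)


class StubRng:
    """Deterministic stand-in yielding fixed r1 then r2 arrays."""

    def __init__(self, r1, r2):
        self._draws = [np.asarray(r1, dtype=float), np.asarray(r2, dtype=float)]

    def uniform(self, size=None):
        return self._draws.pop(0)


def make_state(pop):
    pop = np.asarray(pop, dtype=float)
    fit = np.zeros(pop.shape[0])
    return FOOState(
        population=pop.copy(),
        fitness=fit,
        best_weights=WeightVector.from_array(pop[0]),
        best_fitness=0.0,
        best_history=[0.0],
    )


@pytest.fixture
def labeled_instance(rng):
    vals = rng.dirichlet(np.ones(4), size=(3, 60))
    tensor = ScoreTensor(values=vals)
    labels = rng.integers(0, 4, size=60)
    return tensor, labels


class TestTransformTensor:
    def test_single_model_equals_transforms(self, rng):
        vals = rng.dirichlet(np.ones(4), size=(1, 15))
        pre = precompute_transform_sums(ScoreTensor(values=vals))
        np.testing.assert_allclose(pre.a, transform_exponential(vals[0]), atol=1e-15)
        np.testing.assert_allclose(pre.b, transform_tanh(vals[0]), atol=1e-15)
        np.testing.assert_allclose(pre.c3, transform_sigmoid(vals[0]), atol=1e-15)

    def test_factorized_rank_sum_matches_direct(self, rng):
        # linearity: alpha*A + beta*B + gamma*C3 == Rsum from the full path
        for _ in range(20):
            k, c = rng.integers(1, 5), rng.integers(2, 6)
            vals = rng.dirichlet(np.ones(c), size=(k, 12))
            tensor = ScoreTensor(values=vals)
            pre = precompute_transform_sums(tensor)
            w = np.random.default_rng(int(rng.integers(1 << 16))).dirichlet(np.ones(3))
            wv = WeightVector.from_array(w)
            direct = fuse_batch(tensor, wv)
            fact = wv.alpha * pre.a + wv.beta * pre.b + wv.gamma * pre.c3
            np.testing.assert_allclose(fact, direct.rank_sum, atol=1e-12)
            fact_pred = np.argmin(fact, axis=1)
            np.testing.assert_array_equal(fact_pred, direct.predicted)


class TestFitness:
    def test_exact_fractions(self, labeled_instance):
        tensor, labels = labeled_instance
        pre = precompute_transform_sums(tensor)
        w = WeightVector.uniform()
        pred = fuse_batch(tensor, w).predicted
        # perfect / all-wrong / partial agreement, via doctored labels
        assert evaluate_fitness(w, pre, pred) == 1.0
        wrong = (pred + 1) % 4
        assert evaluate_fitness(w, pre, wrong) == 0.0
        mixed = pred.copy()
        mixed[: len(mixed) // 3] = (mixed[: len(mixed) // 3] + 1) % 4
        expected = 1 - (len(mixed) // 3) / len(mixed)
        assert evaluate_fitness(w, pre, mixed) == pytest.approx(expected)

    def test_label_range_checked(self, labeled_instance):
        tensor, labels = labeled_instance
        pre = precompute_transform_sums(tensor)
        bad = labels.copy()
        bad[0] = 4
        with pytest.raises(ValueError):
            evaluate_fitness(WeightVector.uniform(), pre, bad)


class TestFooStep:
    def test_zero_draws_leave_population_unchanged(self, labeled_instance):
        tensor, labels = labeled_instance
        pre = precompute_transform_sums(tensor)
        pop = np.array([[0.6, 0.3, 0.1], [0.2, 0.2, 0.6], [1 / 3, 1 / 3, 1 / 3]])
        state = make_state(pop)
        foo_step(state, pre, labels, StubRng(np.zeros(3), np.zeros(3)))
        np.testing.assert_array_equal(state.population, pop)

    def test_unit_r1_moves_everyone_to_best(self, labeled_instance):
        tensor, labels = labeled_instance
        pre = precompute_transform_sums(tensor)
        pop = np.array([[0.6, 0.3, 0.1], [0.2, 0.2, 0.6], [0.1, 0.8, 0.1]])
        state = make_state(pop)  # best_weights = pop[0]
        foo_step(state, pre, labels, StubRng(np.ones(3), np.zeros(3)))
        np.testing.assert_allclose(
            state.population, np.tile(pop[0], (3, 1)), atol=1e-12
        )

    def test_collapsed_population_is_fixed_point(self, labeled_instance):
        tensor, labels = labeled_instance
        pre = precompute_transform_sums(tensor)
        p = np.array([0.41, 0.33, 0.26])
        state = make_state(np.tile(p, (4, 1)))
        rng = np.random.default_rng(0)
        for _ in range(5):
            foo_step(state, pre, labels, rng)
        np.testing.assert_array_equal(state.population, np.tile(p, (4, 1)))

    def test_best_history_appends_and_never_decreases(self, labeled_instance):
        tensor, labels = labeled_instance
        pre = precompute_transform_sums(tensor)
        rng = np.random.default_rng(2)
        pop = np.stack([np.random.default_rng(i).dirichlet(np.ones(3)) for i in range(6)])
        state = make_state(pop)
        for _ in range(10):
            foo_step(state, pre, labels, rng)
        h = np.array(state.best_history)
        assert len(h) == 11
        assert np.all(np.diff(h) >= 0)


class TestOptimize:
    def test_config_validation(self):
        with pytest.raises(ValueError):
            FOOConfig(population_size=0)
        with pytest.raises(ValueError):
            FOOConfig(patience=51, max_iterations=50)
        with pytest.raises(ValueError):
            FOOConfig(decision_rule="nope")

    def test_perfect_model_reaches_accuracy_one(self):
        # one model predicts the true class with near-certain scores; the
        # corner (1,0,0) then classifies perfectly, so the optimum is 1.0
        rng = np.random.default_rng(6)
        n, c = 120, 4
        y = rng.integers(0, c, size=n)
        good = np.full((n, c), 0.02)
        good[np.arange(n), y] = 0.94
        noise = rng.dirichlet(np.ones(c), size=n)
        tensor = ScoreTensor(values=np.stack([good, noise]))
        res = optimize(tensor, y, FOOConfig(seed=3, restarts=3))
        assert res.fitness == 1.0

    def test_determinism_bitwise(self, labeled_instance):
        tensor, labels = labeled_instance
        cfg = FOOConfig(seed=42, restarts=2, max_iterations=15)
        a = optimize(tensor, labels, cfg)
        b = optimize(tensor, labels, cfg)
        assert a.weights == b.weights
        assert a.fitness == b.fitness
        assert a.history == b.history
        assert a.restart_index == b.restart_index

    def test_history_monotone_and_elitist(self, labeled_instance):
        tensor, labels = labeled_instance
        res = optimize(tensor, labels, FOOConfig(seed=9))
        h = np.array(res.history)
        assert np.all(np.diff(h) >= 0)
        # elitism: the returned fitness is at least the initial best
        assert res.fitness >= h[0]

    def test_single_class_labels_warn(self, labeled_instance):
        tensor, _ = labeled_instance
        with pytest.warns(UserWarning):
            optimize(tensor, np.zeros(tensor.n_samples, dtype=int),
                     FOOConfig(seed=1, max_iterations=2, patience=1))

    def test_near_grid_oracle_on_seeded_instance(self):
        spec = preset_scenario("complementary_models", seed=4, n_samples=500)
        tensor, y = generate_scenario(spec)
        res = optimize(tensor, y, FOOConfig(seed=4, restarts=5))
        _, grid_fit = grid_search_oracle(tensor, y, step=0.02)
        assert res.fitness >= grid_fit - 0.01
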