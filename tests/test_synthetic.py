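"""Synthetic scenario generator, presets, oracles, benchmark harness."""

import numpy as np
import pytest

from ospreyfuse import (
    FOOConfig,
    ScenarioSpec,
    WeightVector,
    evaluate_fitness,
    generate_scenario,
    grid_search_oracle,
    precompute_transform_sums,
    preset_scenario,
    random_search_baseline,
    run_benchmark,
)
from ospreyfuse.fusion import ROW_SUM_TOL


def single_model_acc(tensor, y, m):
    return float(np.mean(np.argmax(tensor.values[m], axis=1) == y))


class TestGenerator:
    def test_output_passes_ingest_validation_exactly(self):
        tensor, y = generate_scenario(ScenarioSpec(seed=5))
        sums = tensor.values.sum(axis=2)
        assert np.abs(sums - 1).max() < 1e-12  # softmax rows, no renorm needed
        assert np.abs(sums - 1).max() < ROW_SUM_TOL
        assert y.min() >= 0 and y.max() < tensor.n_classes

    def test_determinism_bitwise(self):
        spec = ScenarioSpec(seed=17)
        t1, y1 = generate_scenario(spec)
        t2, y2 = generate_scenario(spec)
        np.testing.assert_array_equal(t1.values, t2.values)
        np.testing.assert_array_equal(y1, y2)

    def test_huge_signal_gives_perfect_models(self):
        spec = ScenarioSpec(
            n_samples=200,
            signal=np.full((3, 4), 50.0),
            shared_noise_scale=0.0,
            private_noise_scale=0.0,
            seed=1,
        )
        tensor, y = generate_scenario(spec)
        for m in range(3):
            assert single_model_acc(tensor, y, m) == 1.0

    def test_zero_signal_is_chance_level(self):
        n, c = 2000, 4
        spec = ScenarioSpec(
            n_samples=n, signal=np.zeros((3, c)), seed=2
        )
        tensor, y = generate_scenario(spec)
        bound = 4 * np.sqrt((1 / c) * (1 - 1 / c) / n)
        for m in range(3):
            assert abs(single_model_acc(tensor, y, m) - 1 / c) < bound

    def test_signal_monotonically_improves_accuracy(self):
        # mean single-model accuracy ordering across 3 signal levels
        means = []
        for sig in (0.5, 1.5, 3.0):
            accs = []
            for seed in range(5):
                spec = ScenarioSpec(
                    n_samples=400, signal=np.full((3, 4), sig), seed=seed
                )
                tensor, y = generate_scenario(spec)
                accs.append(np.mean([single_model_acc(tensor, y, m)
                                     for m in range(3)]))
            means.append(np.mean(accs))
        assert means[0] < means[1] < means[2]

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            ScenarioSpec(n_classes=1)
        with pytest.raises(ValueError):
            ScenarioSpec(signal=np.full((2, 4), 1.0))  # wrong model count
        with pytest.raises(ValueError):
            ScenarioSpec(temperature=0.0)


class TestPresets:
    @pytest.mark.parametrize("name", ["dominant_model", "complementary_models", "all_weak"])
    def test_presets_produce_valid_specs(self, name):
        spec = preset_scenario(name, seed=0)
        assert spec.preset_name == name
        generate_scenario(spec)  # must not raise

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError):
            preset_scenario("nonexistent")

    def test_dominant_model_is_best_single(self):
        # Monte-Carlo over seeds: model 0 beats the weak models on average
        gaps = []
        for seed in range(10):
            tensor, y = generate_scenario(preset_scenario("dominant_model", seed))
            accs = [single_model_acc(tensor, y, m) for m in range(3)]
            gaps.append(accs[0] - max(accs[1:]))
        assert np.mean(gaps) > 0

    def test_complementary_models_individually_capped(self):
        # each model is skilled on 2 of 4 classes, so well below perfect
        tensor, y = generate_scenario(
            preset_scenario("complementary_models", seed=3, n_samples=800)
        )
        for m in range(3):
            assert single_model_acc(tensor, y, m) < 0.85


class TestGridOracle:
    def test_step_validation(self):
        tensor, y = generate_scenario(ScenarioSpec(n_samples=10, seed=0))
        for bad in (0.0, -0.1, 1.5, 0.3):
            with pytest.raises(ValueError):
                grid_search_oracle(tensor, y, step=bad)

    def test_step_one_evaluates_vertices(self):
        tensor, y = generate_scenario(ScenarioSpec(n_samples=50, seed=1))
        w, f = grid_search_oracle(tensor, y, step=1.0)
        arr = w.to_array()
        assert sorted(arr) == [0.0, 0.0, 1.0]
        pre = precompute_transform_sums(tensor)
        best_vertex = max(
            evaluate_fitness(WeightVector.from_array(np.eye(3)[i]), pre, y)
            for i in range(3)
        )
        assert f == best_vertex

    def test_lattice_point_count(self, monkeypatch):
        # step 0.05 visits exactly 21*22/2 = 231 lattice points
        import ospreyfuse.synthetic as syn

        calls = []
        orig = syn._predict

        def counting(w, pre, rule):
            calls.append(1)
            return orig(w, pre, rule)

        monkeypatch.setattr(syn, "_predict", counting)
        tensor, y = generate_scenario(ScenarioSpec(n_samples=20, seed=2))
        grid_search_oracle(tensor, y, step=0.05)
        assert len(calls) == 231

    def test_oracle_dominates_uniform_weights(self):
        tensor, y = generate_scenario(ScenarioSpec(n_samples=100, seed=3))
        # with step 1/3 the uniform vector is on the lattice
        _, f = grid_search_oracle(tensor, y, step=1 / 3)
        pre = precompute_transform_sums(tensor)
        assert f >= evaluate_fitness(WeightVector.uniform(), pre, y)


class TestRandomSearch:
    def test_grid_is_exhaustive_on_its_lattice(self):
        # the grid optimum dominates every lattice point, independently
        # re-enumerated, and never decreases under lattice refinement
        tensor, y = generate_scenario(
            preset_scenario("all_weak", seed=0, n_samples=150)
        )
        pre = precompute_transform_sums(tensor)
        _, grid_f = grid_search_oracle(tensor, y, step=0.05)
        m = 20
        for a in range(m + 1):
            for b in range(m + 1 - a):
                w = np.array([a, b, m - a - b]) / m
                assert evaluate_fitness(WeightVector.from_array(w), pre, y) <= grid_f
        _, finer_f = grid_search_oracle(tensor, y, step=0.025)
        assert finer_f >= grid_f

    def test_random_search_is_deterministic_and_bounded(self):
        tensor, y = generate_scenario(
            preset_scenario("all_weak", seed=1, n_samples=150)
        )
        w1, f1 = random_search_baseline(tensor, y, n_evals=100, seed=3)
        w2, f2 = random_search_baseline(tensor, y, n_evals=100, seed=3)
        assert w1 == w2 and f1 == f2
        pre = precompute_transform_sums(tensor)
        assert f1 == evaluate_fitness(w1, pre, y)


class TestBenchmark:
    def test_report_structure_and_delta_arithmetic(self):
        specs = [preset_scenario("dominant_model", seed=0, n_samples=240)]
        report = run_benchmark(
            specs,
            FOOConfig(seed=0, restarts=2, max_iterations=25, patience=5),
            k_folds=4,
        )
        d = report.to_dict()["scenarios"][0]
        assert d["delta_vs_best_single"] == pytest.approx(
            d["foo_holdout_accuracy"] - max(d["single_model_accuracy"])
        )
        table = report.to_table()
        assert "dominant_model" in table and "delta" in table

    def test_empty_scenario_list_rejected(self):
        with pytest.raises(ValueError):
            run_benchmark([], FOOConfig())
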