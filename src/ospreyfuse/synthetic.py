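"""Synthetic multi-model classifier outputs and optimizer baselines.

The generator stands in for an ensemble of trained probabilistic
classifiers: each "model" emits softmax scores over C classes whose
quality is controlled by a per-model, per-class logit boost applied to
the true class (its "skill"), with a shared Gaussian logit noise term
inducing inter-model correlation and a private noise term per model.

Three presets sketch canonical ensemble regimes:

* ``dominant_model`` — one strong model, two weak ones; fusion should
  at least match the strong model.
* ``complementary_models`` — with C=4 and K=3, model k is skilled only
  on classes {k, k+1 mod 4}; no single model covers all classes but the
  ensemble does, so fusion has guaranteed headroom.
* ``all_weak`` — uniformly low skill.

The module also provides an exhaustive grid oracle on the weight
simplex, a budget-matched random Dirichlet search baseline, and a
benchmark harness that pits FOO against both under a stratified
cross-validation protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import softmax

from .evaluation import stratified_kfold
from .fusion import ScoreTensor
from .optimizer import (
    FOOConfig,
    evaluate_fitness,
    optimize,
    precompute_transform_sums,
    _predict,
)
from .simplex import WeightVector

__all__ = [
    "PRESET_NAMES",
    "ScenarioSpec",
    "generate_scenario",
    "preset_scenario",
    "grid_search_oracle",
    "random_search_baseline",
    "run_benchmark",
    "BenchmarkReport",
]

PRESET_NAMES = ("dominant_model", "complementary_models", "all_weak")


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one synthetic ensemble scenario.

    ``signal`` is a (n_models, n_classes) array of non-negative logit
    boosts added to the true-class logit; larger values mean a more
    skilled model on that class.  ``shared_noise_scale`` controls the
    noise component common to all models (inter-model correlation);
    ``private_noise_scale`` the independent component.  Scores are
    softmax(logits / temperature).
    """

    n_samples: int = 500
    n_classes: int = 4
    n_models: int = 3
    signal: np.ndarray = field(
        default_factory=lambda: np.full((3, 4), 1.5)
    )
    shared_noise_scale: float = 0.5
    private_noise_scale: float = 1.0
    temperature: float = 1.0
    seed: int = 0
    preset_name: str | None = None

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_models < 1 or self.n_classes < 2:
            raise ValueError("need n_samples >= 1, n_models >= 1, n_classes >= 2")
        sig = np.asarray(self.signal, dtype=float)
        if sig.shape != (self.n_models, self.n_classes):
            raise ValueError(
                f"signal must be (n_models, n_classes) = "
                f"({self.n_models}, {self.n_classes}), got {sig.shape}"
            )
        if not np.all(np.isfinite(sig)) or np.any(sig < 0):
            raise ValueError("signal entries must be finite and non-negative")
        for name in ("shared_noise_scale", "private_noise_scale"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative")
        if not (np.isfinite(self.temperature) and self.temperature > 0):
            raise ValueError("temperature must be positive")
        object.__setattr__(self, "signal", sig)

    def to_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "n_classes": self.n_classes,
            "n_models": self.n_models,
            "signal": self.signal.tolist(),
            "shared_noise_scale": self.shared_noise_scale,
            "private_noise_scale": self.private_noise_scale,
            "temperature": self.temperature,
            "seed": self.seed,
            "preset_name": self.preset_name,
        }


def generate_scenario(spec: ScenarioSpec) -> tuple[ScoreTensor, np.ndarray]:
    """Draw labels and per-model softmax score tables for one scenario.

    Labels are uniform over classes.  For model k and sample j,
    ``logits = signal[k, y_j] * onehot(y_j) + shared + private`` and
    ``scores = softmax(logits / temperature)``, so every row sums to one
    exactly (up to float rounding) and ingest never renormalizes.
    Bitwise deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    k, n, c = spec.n_models, spec.n_samples, spec.n_classes
    y = rng.integers(0, c, size=n)
    onehot = np.eye(c)[y]  # (N, C)
    boost = spec.signal[:, y]  # (K, N): per-model boost for each sample's true class
    logits = boost[:, :, None] * onehot[None, :, :]
    logits = logits + spec.shared_noise_scale * rng.standard_normal((1, n, c))
    logits = logits + spec.private_noise_scale * rng.standard_normal((k, n, c))
    scores = softmax(logits / spec.temperature, axis=2)
    tensor = ScoreTensor(
        values=scores,
        model_ids=tuple(f"model_{i}" for i in range(k)),
        class_names=tuple(f"class_{i}" for i in range(c)),
        sample_ids=tuple(f"s{j:06d}" for j in range(n)),
    )
    return tensor, y


def preset_scenario(name: str, seed: int = 0, n_samples: int = 500) -> ScenarioSpec:
    """Fully populated spec for a named canonical scenario."""
    c, k = 4, 3
    if name == "dominant_model":
        signal = np.full((k, c), 0.8)
        signal[0, :] = 2.5
    elif name == "complementary_models":
        signal = np.zeros((k, c))
        for m in range(k):
            signal[m, m % c] = 2.5
            signal[m, (m + 1) % c] = 2.5
    elif name == "all_weak":
        signal = np.full((k, c), 0.7)
    else:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    return ScenarioSpec(
        n_samples=n_samples,
        n_classes=c,
        n_models=k,
        signal=signal,
        shared_noise_scale=0.5,
        private_noise_scale=1.0,
        temperature=1.0,
        seed=seed,
        preset_name=name,
    )


def grid_search_oracle(
    tensor: ScoreTensor,
    labels,
    step: float = 0.02,
    rule: str = "argmin-rsum",
) -> tuple[WeightVector, float]:
    """Exhaustive lattice search over the simplex; brute-force optimum.

    Evaluates every (a*step, b*step, 1-(a+b)*step) with non-negative
    components.  Ties resolve to the lexicographically smallest (a, b)
    visited, i.e. the first maximizer in scan order.
    """
    if not (0.0 < step <= 1.0):
        raise ValueError(f"step must lie in (0, 1], got {step}")
    m = round(1.0 / step)
    if abs(m * step - 1.0) > 1e-9:
        raise ValueError(f"step must divide 1 exactly, got {step}")
    precomp = precompute_transform_sums(tensor)
    y = np.asarray(labels).astype(np.int64)
    best_w: WeightVector | None = None
    best_f = -1.0
    for a in range(m + 1):
        for b in range(m + 1 - a):
            w = np.array([a * step, b * step, 1.0 - (a + b) * step])
            w[2] = max(w[2], 0.0)
            wv = WeightVector.from_array(w / w.sum())
            f = float(np.mean(_predict(wv.to_array(), precomp, rule) == y))
            if f > best_f:
                best_f, best_w = f, wv
    assert best_w is not None
    return best_w, best_f


def random_search_baseline(
    tensor: ScoreTensor,
    labels,
    n_evals: int,
    seed: int,
    rule: str = "argmin-rsum",
) -> tuple[WeightVector, float]:
    """Best-of-N random flat-Dirichlet draws at a fixed evaluation budget."""
    if n_evals < 1:
        raise ValueError("n_evals must be >= 1")
    rng = np.random.default_rng(seed)
    precomp = precompute_transform_sums(tensor)
    y = np.asarray(labels).astype(np.int64)
    best_w: WeightVector | None = None
    best_f = -1.0
    for _ in range(n_evals):
        e = rng.exponential(size=3)
        wv = WeightVector.from_array(e / e.sum())
        f = float(np.mean(_predict(wv.to_array(), precomp, rule) == y))
        if f > best_f:
            best_f, best_w = f, wv
    assert best_w is not None
    return best_w, best_f


@dataclass(frozen=True)
class ScenarioResult:
    """Benchmark quantities for one scenario."""

    spec: ScenarioSpec
    single_model_accuracy: tuple
    uniform_fusion_accuracy: float
    foo_holdout_accuracy: float
    foo_train_fitness: float
    foo_weights: WeightVector
    grid_oracle_accuracy: float
    random_search_accuracy: float
    convergence_history: tuple

    def to_dict(self) -> dict:
        best_single = max(self.single_model_accuracy)
        return {
            "preset": self.spec.preset_name,
            "seed": self.spec.seed,
            "single_model_accuracy": list(self.single_model_accuracy),
            "best_single_model_accuracy": best_single,
            "uniform_fusion_accuracy": self.uniform_fusion_accuracy,
            "foo_holdout_accuracy": self.foo_holdout_accuracy,
            "foo_train_fitness": self.foo_train_fitness,
            "foo_weights": {
                "alpha": self.foo_weights.alpha,
                "beta": self.foo_weights.beta,
                "gamma": self.foo_weights.gamma,
            },
            "grid_oracle_accuracy": self.grid_oracle_accuracy,
            "random_search_accuracy": self.random_search_accuracy,
            "delta_vs_best_single": self.foo_holdout_accuracy - best_single,
            "convergence_history": list(self.convergence_history),
        }


@dataclass(frozen=True)
class BenchmarkReport:
    """Per-scenario results plus a plain-text comparison table."""

    results: tuple

    def to_dict(self) -> dict:
        return {"scenarios": [r.to_dict() for r in self.results]}

    def to_table(self) -> str:
        """Model-vs-ensemble accuracy table with delta columns."""
        lines = [
            f"{'scenario':<24}{'seed':>6}{'best-single':>13}"
            f"{'uniform':>10}{'FOO':>10}{'oracle':>10}{'delta':>9}"
        ]
        for r in self.results:
            best_single = max(r.single_model_accuracy)
            lines.append(
                f"{(r.spec.preset_name or 'custom'):<24}{r.spec.seed:>6}"
                f"{best_single:>13.4f}{r.uniform_fusion_accuracy:>10.4f}"
                f"{r.foo_holdout_accuracy:>10.4f}{r.grid_oracle_accuracy:>10.4f}"
                f"{r.foo_holdout_accuracy - best_single:>+9.4f}"
            )
        return "\n".join(lines) + "\n"


def _single_model_accuracies(tensor: ScoreTensor, y: np.ndarray) -> tuple:
    """Per-model argmax accuracy (no training, so held-out == full-sample)."""
    return tuple(
        float(np.mean(np.argmax(tensor.values[m], axis=1) == y))
        for m in range(tensor.n_models)
    )


def _subset_tensor(tensor: ScoreTensor, idx: np.ndarray) -> ScoreTensor:
    return ScoreTensor(
        values=tensor.values[:, idx, :],
        model_ids=tensor.model_ids,
        class_names=tensor.class_names,
    )


def run_benchmark(
    specs,
    config: FOOConfig = FOOConfig(restarts=5),
    grid_step: float = 0.05,
    k_folds: int = 6,
) -> BenchmarkReport:
    """Benchmark FOO against single models, uniform fusion and baselines.

    For each scenario: generates the data; computes per-model argmax
    accuracies and uniform-average fusion accuracy; runs FOO per
    stratified fold (optimize on the training folds, evaluate the
    held-out fold) and averages the held-out accuracy; evaluates the
    exhaustive grid oracle and a random Dirichlet search at the same
    evaluation budget on the full sample.
    """
    specs = list(specs)
    if not specs:
        raise ValueError("need at least one scenario")
    results = []
    for spec in specs:
        tensor, y = generate_scenario(spec)
        folds = stratified_kfold(y, k_folds, seed=spec.seed)
        single = _single_model_accuracies(tensor, y)

        mean_score = tensor.values.mean(axis=0)
        uniform_acc = float(np.mean(np.argmax(mean_score, axis=1) == y))

        holdout_accs = []
        train_fits = []
        histories: list = []
        last_weights = WeightVector.uniform()
        for f in range(k_folds):
            train = np.flatnonzero(folds != f)
            test = np.flatnonzero(folds == f)
            if test.size == 0 or train.size == 0:
                continue
            res = optimize(
                _subset_tensor(tensor, train),
                y[train],
                replace(config, seed=config.seed + 7919 * f + 104729 * spec.seed),
            )
            test_pre = precompute_transform_sums(_subset_tensor(tensor, test))
            acc = evaluate_fitness(
                res.weights, test_pre, y[test], config.decision_rule
            )
            holdout_accs.append(acc)
            train_fits.append(res.fitness)
            histories.append(res.history)
            last_weights = res.weights
        foo_holdout = float(np.mean(holdout_accs))

        _, grid_acc = grid_search_oracle(
            tensor, y, step=grid_step, rule=config.decision_rule
        )
        m = round(1.0 / grid_step)
        budget = (m + 1) * (m + 2) // 2
        _, rand_acc = random_search_baseline(
            tensor, y, n_evals=budget, seed=spec.seed, rule=config.decision_rule
        )

        results.append(
            ScenarioResult(
                spec=spec,
                single_model_accuracy=single,
                uniform_fusion_accuracy=uniform_acc,
                foo_holdout_accuracy=foo_holdout,
                foo_train_fitness=float(np.mean(train_fits)),
                foo_weights=last_weights,
                grid_oracle_accuracy=grid_acc,
                random_search_accuracy=rand_acc,
                convergence_history=tuple(histories[-1]) if histories else (),
            )
        )
    return BenchmarkReport(results=tuple(results))
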