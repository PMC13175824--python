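"""Fast Osprey Optimization (FOO) of ensemble fusion weights.

FOO is a stripped-down, single-phase variant of the osprey optimization
family: no dual exploration/exploitation phases, no chaotic maps, no
Levy flights, no adaptive parameters.  Each individual is a weight
triple on the simplex; at every iteration individual i moves by a
stochastic contraction toward the global best w* and the population
mean w-bar,

    w_i <- (1 - r1 - r2) * w_i + r1 * w* + r2 * w-bar,   r1, r2 ~ U(0,1),

followed by a clip-and-renormalize projection back onto the simplex.
Fitness is the fused-prediction accuracy on labeled samples.  Because
the per-class rank sum is linear in (alpha, beta, gamma), the three
transform sums are precomputed once (:class:`TransformTensor`), making
each fitness evaluation O(N*C) regardless of the number of models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .fusion import (
    DECISION_RULES,
    ScoreTensor,
    transform_exponential,
    transform_sigmoid,
    transform_tanh,
)
from .simplex import (
    DEFAULT_POLICY,
    ProjectionPolicy,
    WeightVector,
    project_to_simplex,
    sample_uniform_simplex,
)

__all__ = [
    "FOOConfig",
    "FOOState",
    "TransformTensor",
    "OptimizeResult",
    "precompute_transform_sums",
    "evaluate_fitness",
    "foo_step",
    "optimize",
]


@dataclass(frozen=True)
class FOOConfig:
    """Optimizer settings.

    population_size and max_iterations default to 20 and 50 — generous
    for a 3-dimensional simplex search that typically converges well
    inside 25 iterations.  ``patience`` stops a run after that many
    consecutive iterations without a best-fitness improvement greater
    than ``improvement_tolerance`` (patience 0 disables early stopping).
    ``restarts`` independent reseeded runs are performed and the best
    result kept; 1 by default, 5 recommended for benchmarking.
    """

    population_size: int = 20
    max_iterations: int = 50
    patience: int = 10
    improvement_tolerance: float = 1e-6
    restarts: int = 1
    seed: int = 0
    decision_rule: str = "argmin-rsum"

    def __post_init__(self) -> None:
        if self.population_size < 1:
            raise ValueError("population_size must be >= 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.patience < 0 or self.patience > self.max_iterations:
            raise ValueError("need 0 <= patience <= max_iterations")
        if self.improvement_tolerance < 0:
            raise ValueError("improvement_tolerance must be >= 0")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if self.decision_rule not in DECISION_RULES:
            raise ValueError(
                f"unknown decision rule {self.decision_rule!r}; "
                f"choose from {DECISION_RULES}"
            )


@dataclass
class FOOState:
    """Mutable optimizer state for one run.

    ``population`` is (P, 3); ``fitness`` is the accuracy of each
    individual; ``best_weights``/``best_fitness`` track the global best
    ever evaluated; ``best_history`` records the best fitness after
    initialization and after each iteration and is non-decreasing.
    """

    population: np.ndarray
    fitness: np.ndarray
    best_weights: WeightVector
    best_fitness: float
    iteration: int = 0
    best_history: list = field(default_factory=list)

    @property
    def population_mean(self) -> np.ndarray:
        return self.population.mean(axis=0)


@dataclass(frozen=True)
class TransformTensor:
    """Weight-independent per-(sample, class) transform sums.

    A = sum_k R1, B = sum_k R2, C3 = sum_k R3 and the per-class mean
    score, each (N, C).  For any weights, alpha*A + beta*B + gamma*C3
    reproduces the rank sum computed directly from the score tensor.
    """

    a: np.ndarray
    b: np.ndarray
    c3: np.ndarray
    mean_score: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.a.shape[0]

    @property
    def n_classes(self) -> int:
        return self.a.shape[1]


def precompute_transform_sums(tensor: ScoreTensor) -> TransformTensor:
    """Factor the fusion pipeline into weight-independent sums.

    One O(N*C*K) pass; afterwards each candidate's fitness costs O(N*C).
    """
    v = tensor.values
    return TransformTensor(
        a=transform_exponential(v).sum(axis=0),
        b=transform_tanh(v).sum(axis=0),
        c3=transform_sigmoid(v).sum(axis=0),
        mean_score=v.mean(axis=0),
    )


def _check_labels(labels, n_samples: int, n_classes: int) -> np.ndarray:
    y = np.asarray(labels)
    if y.shape != (n_samples,):
        raise ValueError(f"labels must have shape ({n_samples},), got {y.shape}")
    y = y.astype(np.int64)
    if y.size and (y.min() < 0 or y.max() >= n_classes):
        raise ValueError(
            f"labels must lie in [0, {n_classes - 1}]; got range "
            f"[{y.min()}, {y.max()}]"
        )
    return y


def _predict(
    weights_arr: np.ndarray, precomp: TransformTensor, rule: str
) -> np.ndarray:
    al, be, ga = weights_arr
    rank_sum = al * precomp.a + be * precomp.b + ga * precomp.c3
    if rule == "argmin-rsum":
        return np.argmin(rank_sum, axis=1)
    if rule == "argmin-f":
        return np.argmin(rank_sum * (1.0 - precomp.mean_score), axis=1)
    if rule == "argmax-mean":
        return np.argmax(precomp.mean_score, axis=1)
    raise ValueError(f"unknown decision rule {rule!r}")


def evaluate_fitness(
    weights: WeightVector,
    precomp: TransformTensor,
    labels,
    rule: str = "argmin-rsum",
) -> float:
    """Fused-prediction accuracy (fraction of samples with c-hat == y)."""
    y = _check_labels(labels, precomp.n_samples, precomp.n_classes)
    pred = _predict(weights.to_array(), precomp, rule)
    return float(np.mean(pred == y))


def _init_state(
    precomp: TransformTensor,
    labels: np.ndarray,
    rng: np.random.Generator,
    config: FOOConfig,
) -> FOOState:
    pop = np.stack(
        [
            sample_uniform_simplex(rng).to_array()
            for _ in range(config.population_size)
        ]
    )
    fit = np.array(
        [
            float(
                np.mean(_predict(pop[i], precomp, config.decision_rule) == labels)
            )
            for i in range(config.population_size)
        ]
    )
    best_i = int(np.argmax(fit))
    state = FOOState(
        population=pop,
        fitness=fit,
        best_weights=WeightVector.from_array(pop[best_i]),
        best_fitness=float(fit[best_i]),
    )
    state.best_history.append(state.best_fitness)
    return state


def foo_step(
    state: FOOState,
    precomp: TransformTensor,
    labels,
    rng: np.random.Generator,
    policy: ProjectionPolicy = DEFAULT_POLICY,
    rule: str = "argmin-rsum",
    improvement_tolerance: float = 1e-6,
) -> FOOState:
    """One synchronous FOO iteration, mutating and returning ``state``.

    All individuals see the same attractors (w*, w-bar computed before
    any move); draws r1, r2 are fresh scalars per individual; moves are
    unconditional (no greedy per-individual acceptance) — the global
    best is tracked separately and only replaced on an improvement
    strictly greater than ``improvement_tolerance``.
    """
    y = _check_labels(labels, precomp.n_samples, precomp.n_classes)
    pop = state.population
    p = pop.shape[0]
    w_best = state.best_weights.to_array()
    w_mean = pop.mean(axis=0)
    r1 = rng.uniform(size=p)
    r2 = rng.uniform(size=p)
    # equivalent to (1 - r1 - r2) w + r1 w* + r2 w-bar, written so a fully
    # collapsed population (w = w* = w-bar) is a bitwise fixed point
    moved = (
        pop
        + r1[:, None] * (w_best[None, :] - pop)
        + r2[:, None] * (w_mean[None, :] - pop)
    )
    new_pop = np.empty_like(pop)
    new_fit = np.empty(p)
    for i in range(p):
        w = project_to_simplex(moved[i], policy).to_array()
        new_pop[i] = w
        new_fit[i] = float(np.mean(_predict(w, precomp, rule) == y))
    state.population = new_pop
    state.fitness = new_fit
    best_i = int(np.argmax(new_fit))
    if new_fit[best_i] > state.best_fitness + improvement_tolerance:
        state.best_fitness = float(new_fit[best_i])
        state.best_weights = WeightVector.from_array(new_pop[best_i])
    state.iteration += 1
    state.best_history.append(state.best_fitness)
    return state


@dataclass(frozen=True)
class OptimizeResult:
    """Best weights and fitness across restarts, with diagnostics."""

    weights: WeightVector
    fitness: float
    history: tuple
    restart_index: int
    config: FOOConfig

    def to_dict(self) -> dict:
        return {
            "best_weights": {
                "alpha": self.weights.alpha,
                "beta": self.weights.beta,
                "gamma": self.weights.gamma,
            },
            "best_fitness": self.fitness,
            "best_history": list(self.history),
            "restart_index": self.restart_index,
            "config": {
                "population_size": self.config.population_size,
                "max_iterations": self.config.max_iterations,
                "patience": self.config.patience,
                "improvement_tolerance": self.config.improvement_tolerance,
                "restarts": self.config.restarts,
                "seed": self.config.seed,
                "decision_rule": self.config.decision_rule,
            },
        }


def optimize(
    tensor: ScoreTensor,
    labels,
    config: FOOConfig = FOOConfig(),
    policy: ProjectionPolicy = DEFAULT_POLICY,
) -> OptimizeResult:
    """Search the simplex for the weight triple maximizing fused accuracy.

    Runs ``config.restarts`` independent FOO runs with seeds derived
    deterministically from ``config.seed`` and returns the best result
    (first restart wins ties).  Fully reproducible for a fixed config.
    """
    if tensor.n_samples == 0:
        raise ValueError("empty data: need at least one labeled sample")
    y = _check_labels(labels, tensor.n_samples, tensor.n_classes)
    if np.unique(y).size < 2:
        warnings.warn(
            "labels contain a single class; fitness is well defined but "
            "the optimum is degenerate",
            UserWarning,
            stacklevel=2,
        )
    precomp = precompute_transform_sums(tensor)
    rule = config.decision_rule

    best: OptimizeResult | None = None
    for r in range(config.restarts):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, r]))
        state = _init_state(precomp, y, rng, config)
        stall = 0
        for _ in range(config.max_iterations):
            before = state.best_fitness
            foo_step(
                state,
                precomp,
                y,
                rng,
                policy,
                rule,
                config.improvement_tolerance,
            )
            if state.best_fitness > before + config.improvement_tolerance:
                stall = 0
            else:
                stall += 1
            if config.patience and stall >= config.patience:
                break
        if best is None or state.best_fitness > best.fitness:
            best = OptimizeResult(
                weights=state.best_weights,
                fitness=state.best_fitness,
                history=tuple(state.best_history),
                restart_index=r,
                config=config,
            )
    assert best is not None
    return best
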