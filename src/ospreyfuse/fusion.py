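"""Non-linear rank transforms and weighted score fusion.

Each base classifier emits a per-class probability vector
``S = [s_1, ..., s_C]``.  Instead of averaging raw probabilities, the
fusion stage maps every score through three monotone non-linear
transforms ("rank indicators"):

    R1(s) = 1 - exp(-(s - 1)^2 / 2)     exponential decay, decreasing in s
    R2(s) = 1 - tanh((s - 1)^2 / 2)     bounded suppression, increasing in s
    R3(s) = 1 / (1 + exp(-s))           sigmoid activation, increasing in s

and blends them with convex weights: R = alpha*R1 + beta*R2 + gamma*R3.
Across K models the per-class rank sum, complement score and fused
confidence are

    Rsum(i) = sum_k R^(k)(i)
    Ssum(i) = 1 - (1/K) sum_k s_i^(k)
    F(i)    = Rsum(i) * Ssum(i)

and the default decision rule predicts argmin_i Rsum(i).  Two alternate
rules are exposed: ``argmin-f`` (argmin of F) and ``argmax-mean`` (plain
probability averaging).  Note R1 decreases with confidence while R2/R3
increase; the formulas are implemented verbatim and the weight optimizer
resolves the mix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simplex import WeightVector

__all__ = [
    "DECISION_RULES",
    "ScoreTensor",
    "FusionResult",
    "transform_exponential",
    "transform_tanh",
    "transform_sigmoid",
    "combined_rank",
    "aggregate_sample",
    "fuse_batch",
]

#: selectable decision rules; the first is the default
DECISION_RULES = ("argmin-rsum", "argmin-f", "argmax-mean")

#: per-row probability sums may deviate from one by this much before the
#: ingest path renormalizes with a warning (see io module)
ROW_SUM_TOL = 1e-3


@dataclass(frozen=True)
class ScoreTensor:
    """Per-model, per-sample, per-class probability scores.

    ``values`` has shape (K, N, C): K models, N samples, C classes.
    All entries lie in [0, 1] and each (model, sample) row sums to one
    within ``ROW_SUM_TOL`` (the ingest path renormalizes looser rows).
    """

    values: np.ndarray
    model_ids: tuple = ()
    class_names: tuple = ()
    sample_ids: tuple = ()

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3:
            raise ValueError(f"score tensor must be 3-d (K,N,C), got {v.shape}")
        k, n, c = v.shape
        if k < 1 or n < 1 or c < 2:
            raise ValueError(f"need K>=1, N>=1, C>=2; got K={k}, N={n}, C={c}")
        if not np.all(np.isfinite(v)):
            raise ValueError("score tensor contains non-finite values")
        if v.min() < 0.0 or v.max() > 1.0:
            raise ValueError(
                f"scores outside [0,1]: min={v.min()}, max={v.max()}"
            )
        rowsums = v.sum(axis=2)
        dev = np.abs(rowsums - 1.0).max()
        if dev > ROW_SUM_TOL:
            raise ValueError(
                f"score rows must sum to 1 within {ROW_SUM_TOL} "
                f"(max deviation {dev:.3g}); renormalize on ingest"
            )
        object.__setattr__(self, "values", v)
        object.__setattr__(
            self,
            "model_ids",
            tuple(self.model_ids) or tuple(f"model_{i}" for i in range(k)),
        )
        object.__setattr__(
            self,
            "class_names",
            tuple(self.class_names) or tuple(f"class_{i}" for i in range(c)),
        )
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        if len(self.model_ids) != k:
            raise ValueError("model_ids length does not match K")
        if len(self.class_names) != c:
            raise ValueError("class_names length does not match C")
        if self.sample_ids and len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match N")

    @property
    def n_models(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_classes(self) -> int:
        return self.values.shape[2]


@dataclass(frozen=True)
class FusionResult:
    """Fused per-sample quantities for one weight vector and rule.

    All arrays are (N, C) except ``predicted``, which is (N,) integer
    class indices.  ``r_exp``/``r_tanh``/``r_sig`` hold the per-class
    transform sums over models, so ``rank_sum`` is exactly their convex
    combination under the fusion weights.
    """

    r_exp: np.ndarray
    r_tanh: np.ndarray
    r_sig: np.ndarray
    rank_sum: np.ndarray
    score_complement: np.ndarray
    fused_confidence: np.ndarray
    predicted: np.ndarray
    rule: str = "argmin-rsum"
    weights: WeightVector = field(default_factory=WeightVector.uniform)


def _check_scores(s: np.ndarray) -> np.ndarray:
    s = np.asarray(s, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    if s.size and (s.min() < 0.0 or s.max() > 1.0):
        raise ValueError(
            f"scores must lie in [0,1]; got range [{s.min()}, {s.max()}]"
        )
    return s


def transform_exponential(s):
    """Exponential-decay rank indicator ``1 - exp(-(s-1)^2/2)``.

    Strictly decreasing on [0, 1]; 0 at full confidence, ~0.3935 at s=0.
    """
    s = _check_scores(s)
    return 1.0 - np.exp(-((s - 1.0) ** 2) / 2.0)


def transform_tanh(s):
    """Tanh rank indicator ``1 - tanh((s-1)^2/2)``; increasing on [0, 1]."""
    s = _check_scores(s)
    return 1.0 - np.tanh(((s - 1.0) ** 2) / 2.0)


def transform_sigmoid(s):
    """Sigmoid rank indicator ``1/(1+exp(-s))``; increasing on [0, 1]."""
    s = _check_scores(s)
    return 1.0 / (1.0 + np.exp(-s))


def combined_rank(scores, weights: WeightVector) -> np.ndarray:
    """Convex combination of the three rank transforms, elementwise.

    R(i) = alpha*R1(s_i) + beta*R2(s_i) + gamma*R3(s_i); linear in the
    weights for fixed scores.
    """
    s = _check_scores(scores)
    return (
        weights.alpha * transform_exponential(s)
        + weights.beta * transform_tanh(s)
        + weights.gamma * transform_sigmoid(s)
    )


def _decide(
    rank_sum: np.ndarray,
    fused: np.ndarray,
    mean_score: np.ndarray,
    rule: str,
) -> np.ndarray:
    # np.argmin/argmax return the lowest index on ties, the stated tie-break
    if rule == "argmin-rsum":
        return np.argmin(rank_sum, axis=-1)
    if rule == "argmin-f":
        return np.argmin(fused, axis=-1)
    if rule == "argmax-mean":
        return np.argmax(mean_score, axis=-1)
    raise ValueError(f"unknown decision rule {rule!r}; choose from {DECISION_RULES}")


def fuse_batch(
    tensor: ScoreTensor,
    weights: WeightVector,
    rule: str = "argmin-rsum",
) -> FusionResult:
    """Fuse all N samples of a score tensor under one weight vector.

    Vectorized over samples; row j of the result equals
    :func:`aggregate_sample` applied to sample j alone.
    """
    if rule not in DECISION_RULES:
        raise ValueError(f"unknown decision rule {rule!r}; choose from {DECISION_RULES}")
    v = tensor.values  # (K, N, C)
    a = transform_exponential(v).sum(axis=0)  # (N, C)
    b = transform_tanh(v).sum(axis=0)
    c3 = transform_sigmoid(v).sum(axis=0)
    mean_score = v.mean(axis=0)
    rank_sum = weights.alpha * a + weights.beta * b + weights.gamma * c3
    score_complement = 1.0 - mean_score
    fused = rank_sum * score_complement
    predicted = _decide(rank_sum, fused, mean_score, rule)
    return FusionResult(
        r_exp=a,
        r_tanh=b,
        r_sig=c3,
        rank_sum=rank_sum,
        score_complement=score_complement,
        fused_confidence=fused,
        predicted=predicted,
        rule=rule,
        weights=weights,
    )


def aggregate_sample(
    scores, weights: WeightVector, rule: str = "argmin-rsum"
) -> FusionResult:
    """Fuse one sample's K per-class score vectors into a class decision.

    ``scores`` is (K, C): one row per model.  Returns a single-row
    :class:`FusionResult` (arrays keep their leading N=1 axis dropped to
    shape (C,); ``predicted`` is a scalar array).
    """
    s = np.asarray(scores, dtype=float)
    if s.ndim == 1:
        s = s[None, :]
    if s.ndim != 2:
        raise ValueError(f"expected (K, C) scores for one sample, got {s.shape}")
    if s.shape[0] == 0:
        raise ValueError("empty ensemble: need at least one model's scores")
    tensor = ScoreTensor(values=s[:, None, :])
    res = fuse_batch(tensor, weights, rule)
    return FusionResult(
        r_exp=res.r_exp[0],
        r_tanh=res.r_tanh[0],
        r_sig=res.r_sig[0],
        rank_sum=res.rank_sum[0],
        score_complement=res.score_complement[0],
        fused_confidence=res.fused_confidence[0],
        predicted=res.predicted[0],
        rule=rule,
        weights=weights,
    )
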