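"""Fusion-weight vectors on the 2-simplex.

The ensemble fusion stage blends three non-linear rank transforms of
classifier confidences with convex coefficients (alpha, beta, gamma).
The feasible region is therefore the probability simplex

    Delta^2 = { (a, b, g) : a, b, g >= 0, a + b + g = 1 }.

This module owns the weight-vector type, its validation tolerances,
the clip-and-renormalize projection used after every optimizer move,
and uniform (flat-Dirichlet) sampling used to initialize populations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SUM_TOL",
    "WeightVector",
    "ProjectionPolicy",
    "project_to_simplex",
    "sample_uniform_simplex",
]

#: absolute tolerance on |alpha + beta + gamma - 1| for a valid weight vector
SUM_TOL = 1e-9

#: tolerances for *accepting* an externally supplied triple: components may
#: dip to -1e-9 and the sum may be off by 1e-6; such vectors are silently
#: projected.  Larger violations raise.
_ACCEPT_NEG_TOL = 1e-9
_ACCEPT_SUM_TOL = 1e-6


@dataclass(frozen=True)
class ProjectionPolicy:
    """Numerical policy for the simplex projection.

    Parameters
    ----------
    epsilon
        Small positive guard added to the denominator so the
        renormalization never divides by zero.  Must lie in (0, 1e-6).
    """

    epsilon: float = 1e-12

    def __post_init__(self) -> None:
        if not (0.0 < self.epsilon < 1e-6):
            raise ValueError(
                f"epsilon must be in (0, 1e-6), got {self.epsilon!r}"
            )


DEFAULT_POLICY = ProjectionPolicy()


@dataclass(frozen=True)
class WeightVector:
    """A convex fusion-weight triple (alpha, beta, gamma) on Delta^2.

    ``alpha`` weighs the exponential-decay rank transform, ``beta`` the
    tanh transform and ``gamma`` the sigmoid transform.  Construction
    validates non-negativity and sum-to-one; triples within the accept
    band (components >= -1e-9, sum within 1e-6 of one) are silently
    projected back onto the simplex.
    """

    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        arr = np.array([self.alpha, self.beta, self.gamma], dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite weight components: {arr}")
        s = float(arr.sum())
        if np.any(arr < -_ACCEPT_NEG_TOL) or abs(s - 1.0) > _ACCEPT_SUM_TOL:
            raise ValueError(
                f"weights {arr.tolist()} violate simplex constraints "
                f"(component >= -{_ACCEPT_NEG_TOL}, |sum-1| <= {_ACCEPT_SUM_TOL})"
            )
        if np.any(arr < 0.0) or abs(s - 1.0) > SUM_TOL:
            arr = _project_array(arr, DEFAULT_POLICY)
            object.__setattr__(self, "alpha", float(arr[0]))
            object.__setattr__(self, "beta", float(arr[1]))
            object.__setattr__(self, "gamma", float(arr[2]))

    # -- conversions ---------------------------------------------------

    def to_array(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.gamma], dtype=float)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "WeightVector":
        a = np.asarray(arr, dtype=float).ravel()
        if a.shape != (3,):
            raise ValueError(f"expected 3 components, got shape {a.shape}")
        return cls(float(a[0]), float(a[1]), float(a[2]))

    @classmethod
    def uniform(cls) -> "WeightVector":
        return cls(1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0)

    # -- JSON round-trip ----------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {"alpha": self.alpha, "beta": self.beta, "gamma": self.gamma}
        )

    @classmethod
    def from_json(cls, text: str) -> "WeightVector":
        obj = json.loads(text)
        return cls(float(obj["alpha"]), float(obj["beta"]), float(obj["gamma"]))


def _project_array(raw: np.ndarray, policy: ProjectionPolicy) -> np.ndarray:
    """Clip negatives, renormalize with an epsilon-guarded denominator."""
    clipped = np.maximum(raw, 0.0)
    s = float(clipped.sum())
    if s < policy.epsilon:
        return np.full(3, 1.0 / 3.0)
    out = clipped / (s + policy.epsilon)
    # The guarded division leaves a residual of eps/(s+eps); for near-zero
    # post-clip sums that residual can exceed the simplex tolerance, so one
    # exact renormalization is applied in that (degenerate) regime only.
    total = float(out.sum())
    if abs(total - 1.0) > SUM_TOL:
        out = out / total
    return out


def project_to_simplex(
    raw, policy: ProjectionPolicy = DEFAULT_POLICY
) -> WeightVector:
    """Project an arbitrary finite triple onto the probability simplex.

    The rule is the clip-and-renormalize map used after every optimizer
    update: negative components are clipped to zero, then the triple is
    divided by its sum plus ``policy.epsilon``.  If everything clips away
    (post-clip sum below epsilon) the uniform vector (1/3, 1/3, 1/3) is
    returned so the search always stays feasible.

    The map is idempotent: a valid weight vector is returned unchanged up
    to 1e-12 per component.

    Raises
    ------
    ValueError
        If any input component is non-finite or the input is not a
        length-3 triple.
    """
    arr = np.asarray(raw, dtype=float).ravel()
    if arr.shape != (3,):
        raise ValueError(f"expected a real triple, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"non-finite input to projection: {arr.tolist()}")
    # already-feasible vectors pass through untouched, making the map an
    # exact identity on the simplex (and hence exactly idempotent)
    if np.all(arr >= 0.0) and abs(float(arr.sum()) - 1.0) <= SUM_TOL:
        return WeightVector(float(arr[0]), float(arr[1]), float(arr[2]))
    out = _project_array(arr, policy)
    return WeightVector(float(out[0]), float(out[1]), float(out[2]))


def sample_uniform_simplex(rng: np.random.Generator) -> WeightVector:
    """Draw one weight vector uniformly from the simplex (flat Dirichlet).

    Uses the normalized-exponential-spacings construction, equivalent to
    Dirichlet(1, 1, 1); component mean is 1/3 and variance 1/18.
    Deterministic given the generator state.
    """
    e = rng.exponential(scale=1.0, size=3)
    return WeightVector.from_array(e / e.sum())
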