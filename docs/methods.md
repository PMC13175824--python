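# Methods

## Problem

An ensemble of K probabilistic classifiers (in the motivating application,
CNNs grading peripheral blood smear images into four leukemia-related
classes) each emits a per-class probability vector per sample. `ospreyfuse`
fuses those score vectors into a single class decision by (1) mapping every
score through three fixed non-linear "rank" transforms, (2) blending the
transforms with a learned convex weight triple, and (3) aggregating across
models. The weight triple is the only learned quantity; it is fit by a
small population-based optimizer (Fast Osprey Optimization, FOO) that
maximizes fused classification accuracy on labeled data.

## Fusion model

For a score s in [0, 1]:

- R1(s) = 1 − exp(−(s−1)²/2) — decreasing in s, range [0, 1−e^(−1/2)]
- R2(s) = 1 − tanh((s−1)²/2) — increasing, range [1−tanh(1/2), 1]
- R3(s) = 1/(1+e^(−s)) — increasing, range [1/2, 1/(1+e^(−1))]

Per class i: R(i) = α·R1 + β·R2 + γ·R3 with (α, β, γ) on the simplex Δ².
Across models: Rsum(i) = Σ_k R^(k)(i), Ssum(i) = 1 − mean_k s_i^(k),
F(i) = Rsum(i)·Ssum(i). The default decision rule is argmin_i Rsum(i),
implemented verbatim; `argmin-f` (uses F) and `argmax-mean` (plain
probability averaging) are selectable alternatives because F is defined by
the formulas yet unused by the printed decision rule, and averaging is the
natural baseline. Ties break to the lowest class index everywhere.

Two properties worth stating plainly:

- **Opposing monotonic directions.** R1 falls with confidence while R2 and
  R3 rise with it, so the direction of argmin(Rsum) depends on the weight
  mix: with α dominant it selects the jointly most-confident class; tipped
  toward β/γ it inverts. The transforms are implemented exactly as given
  and the optimizer resolves the mix — empirically the learned optimum
  puts most mass on α, with β trading off against it.
- **No per-model weighting.** The triple weights the three transforms and
  is shared across models (the search space is deliberately
  3-dimensional). Fusion therefore cannot down-weight a weak ensemble
  member: with one strong and two weak models the fused decision can fall
  below the strong model alone. This is a structural property of the
  weight space, visible in the `dominant_model` benchmark preset, not an
  optimizer failure.

Because Rsum is linear in (α, β, γ), the per-(sample, class) transform
sums A = Σ_k R1, B = Σ_k R2, C3 = Σ_k R3 and the mean score are
precomputed once (`TransformTensor`); each candidate's fitness then costs
O(N·C) independent of K. Tests assert the factorized path agrees with the
direct evaluation to 1e−12 and decision-for-decision.

## Optimizer

Each individual is a weight triple. Per iteration, synchronously for all
individuals (attractors frozen at the start of the step):

    w_i ← w_i + r1·(w* − w_i) + r2·(w̄ − w_i),   r1, r2 ~ U(0,1) scalars,

followed by projection onto the simplex: clip negatives to zero, divide by
(sum + ε). Moves are unconditional; the global best is tracked separately
and replaced only on an improvement strictly greater than
`improvement_tolerance` (ties keep the incumbent — accuracy is a step
function of the weights and churn on plateaus helps nothing). The update is
written in the difference form above (algebraically identical to the convex
combination `(1−r1−r2)w + r1 w* + r2 w̄`) so that a fully collapsed
population is a bitwise fixed point. Since r1 + r2 may exceed 1 the
"convex" combination can overshoot past the attractors; the projection
absorbs this, and in practice it supplies the only exploration pressure the
single-phase rule has.

Defaults: population 20, max 50 iterations, patience 10 at tolerance 1e−6,
1 restart (5 recommended for benchmarking — the accuracy landscape is
piecewise constant and mildly multimodal, and independent reseeded restarts
are the cheapest insurance against attractor collapse). Runs typically
converge well inside 25 iterations. `patience = 0` disables early stopping
(a zero-length stall window would otherwise stop every run immediately).
Restart seeds derive from `(seed, restart_index)` via `SeedSequence`, so
results are bitwise reproducible.

Initialization is uniform on the simplex (flat Dirichlet via normalized
exponential spacings), chosen over normalizing a uniform cube draw because
the latter is biased toward the simplex center.

## Projection numerics

ε = 1e−12: small enough to perturb valid weights by < 1e−11, large enough
to guard 0/0. If everything clips away (post-clip sum < ε) the projection
returns the uniform vector so the search stays feasible. Two guards beyond
the bare formula: (1) an already-feasible vector passes through untouched,
making the map an exact identity on the simplex (hence exactly
idempotent); (2) for near-degenerate inputs whose post-clip sum lies in
(ε, ~1e−3), the ε-guarded division alone would leave the result short of
sum 1 by more than the 1e−9 simplex tolerance, so one exact renormalization
is applied in that regime only. Externally supplied triples with
components ≥ −1e−9 and sum within 1e−6 of 1 are silently projected; larger
violations raise.

## Evaluation

Accuracy is trace/N of the confusion matrix; per-class precision/recall
divide the diagonal by column/row sums with the 0-when-empty convention
(flagged classes are listed in the report); macro metrics are unweighted
class means — chosen as primary because the synthetic scenarios (and the
motivating application after balancing) are class-balanced, making macro ≈
weighted; per-class values are always emitted so any other averaging can be
recomputed. Cohen's kappa is (p_o − p_e)/(1 − p_e) with marginal-product
p_e; the degenerate p_e = 1 case returns 1 if p_o = 1 else 0. The metric
path is cross-checked against scikit-learn in the tests, and accuracy is
additionally required to agree with the optimizer's fitness path to 1e−12
(two independent code routes to the same number).

Stratified k-fold (default k = 6, matching the motivating protocol):
per-class seeded shuffle, then round-robin assignment over folds, so
within-class fold sizes differ by at most one and the folds partition the
indices. k larger than the smallest class count warns and proceeds.

## Synthetic generator

Labels are uniform over C classes. For model k and sample j, logits are
`signal[k, y_j] · onehot(y_j) + shared_noise + private_noise` with
independent standard Gaussians scaled by `shared_noise_scale` (common to
all models — induces inter-model correlation) and `private_noise_scale`;
scores are softmax(logits/temperature). This is the simplest generator
with controllable per-model per-class skill and correlation; rows sum to
one exactly, so ingest never renormalizes.

Preset conditions (chosen once as realistic mid-skill regimes, far from
both chance and ceiling): skilled-class boost 2.5, weak boost 0.8
(`dominant_model`) or 0.7 (`all_weak`), shared noise 0.5, private noise
1.0, temperature 1.0. Under `complementary_models` each model is skilled
on 2 of 4 classes (single-model accuracy ≈ 0.56) while the ensemble covers
all classes (fused ≈ 0.76–0.79): fusion headroom is built into the
construction, not tuned.

What the generator does **not** emulate: calibration error shared across
classes, label noise, class imbalance, heavy-tailed confidence
distributions, and the feature-level correlations of real CNNs trained on
the same images (only additive logit correlation). Passing tests
demonstrate the pipeline's internal correctness and the optimizer's
near-optimality on this family, not performance on any real imaging
dataset.

## Baselines and benchmark protocol

The grid oracle exhaustively evaluates the lattice {(a·h, b·h, 1−(a+b)·h)}
(h = 0.02 → 1,326 points) and upper-bounds every on-lattice weight; the
random-search baseline draws flat-Dirichlet candidates at a matched
evaluation budget. Note the grid bounds only its lattice: a continuous
random draw can legitimately beat a coarse grid on this step-function
landscape, so the tests assert lattice exhaustiveness and refinement
monotonicity rather than global dominance. Benchmarks optimize on the
training folds of a stratified 6-fold split and report held-out accuracy;
single-model argmax baselines involve no training, so their held-out and
full-sample accuracies coincide. Problem sizes used by the shipped tests
and the reproduction script — N = 500–1,200, C = 4, K = 3, 5–10 seeds —
were chosen to make the Monte-Carlo comparisons stable at desk scale.

## Known limitations

- The shared-transform weight space cannot express per-model reliability
  (see above); per-model or per-class weight matrices are out of scope.
- Accuracy-as-fitness is blind to calibration; input probabilities are
  taken as given (no temperature scaling).
- The single-phase update has no explicit exploration mechanism beyond the
  stochastic overshoot; on strongly multimodal fitness surfaces restarts
  are the only remedy offered.
- Inference-time/throughput comparisons are out of scope (hardware-bound).
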