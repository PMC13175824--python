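"""Learn fusion weights with FOO on a complementary ensemble.

Generates three synthetic classifiers that are each skilled on only two
of four classes, runs Fast Osprey Optimization over the weight simplex,
and compares the fused accuracy against every single model, plain
probability averaging, and the exhaustive grid oracle.
"""

import numpy as np

from ospreyfuse import (
    FOOConfig,
    generate_scenario,
    grid_search_oracle,
    optimize,
    preset_scenario,
)

spec = preset_scenario("complementary_models", seed=0, n_samples=600)
tensor, y = generate_scenario(spec)

for m in range(tensor.n_models):
    acc = np.mean(np.argmax(tensor.values[m], axis=1) == y)
    print(f"single model {m} argmax accuracy: {acc:.4f}")

uniform = np.mean(np.argmax(tensor.values.mean(axis=0), axis=1) == y)
print(f"uniform probability-averaging accuracy: {uniform:.4f}")

result = optimize(tensor, y, FOOConfig(seed=1, restarts=3))
w = result.weights
print(f"FOO best weights: alpha={w.alpha:.4f}, beta={w.beta:.4f}, "
      f"gamma={w.gamma:.4f}")
print(f"FOO fused accuracy: {result.fitness:.4f} "
      f"(found in {len(result.history) - 1} iterations)")

_, grid_fit = grid_search_oracle(tensor, y, step=0.02)
print(f"exhaustive grid oracle (step 0.02): {grid_fit:.4f}")

# Each model alone tops out near 0.56 because it only separates half the
# classes; fusing all three with learned weights recovers ~0.79, slightly
# above the lattice optimum since FOO searches the continuous simplex.
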