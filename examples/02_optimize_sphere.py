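"""Minimize the sphere benchmark with the Aquila Optimizer.

The AO alternates four eagle-hunting position updates — two explorative
for the first two-thirds of iterations, two exploitative afterwards —
with greedy acceptance, so the best-fitness trace is non-increasing.
"""

import numpy as np

from dermao.ao import AOConfig, Bounds, optimize

config = AOConfig(pop_size=30, max_iter=500, seed=1)
result = optimize(
    lambda x: float(np.sum(x**2)), Bounds.cube(5, -10.0, 10.0), config
)

print(f"best fitness after {config.max_iter} iterations: {result.best_fitness:.3e}")
print(f"best position: {np.round(result.best_position, 6)}")
print(f"objective evaluations: {result.evaluations}")
marks = [0, 50, 100, 250, 500]
print("convergence:", {t: f"{result.history[t]:.3e}" for t in marks})
print("(the trace is the best-so-far value, so it can only decrease;"
      " values near zero mean the optimum at the origin was found)")
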