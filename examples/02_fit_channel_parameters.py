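"""Recover channel parameters from synthetic voltage-clamp data with the GA.

Generates a noise-free clamp dataset from the KCNE3-V17M I_Kr parameter set,
then fits the three free parameters with the genetic algorithm (smaller
population than the study default so the example runs in ~10 s) and prints
the recovered values against the ground truth.
"""

from atrialab import GAConfig, evolve, get_mutation
from atrialab.synth import gen_clamp_dataset

truth = get_mutation("KCNE3-V17M")
dataset, _ = gen_clamp_dataset(truth, channel="IKr", noise_sd=0.0, seed=1)

free = ["p3r", "p6r", "p8r"]
fit = evolve(GAConfig(population=150, generations=15, seed=0), free, [dataset])

print(f"best weighted-RMSE score: {fit.best_score:.3e}")
print(f"{'param':6s} {'truth':>8s} {'fitted':>8s}")
for name in free:
    print(f"{name:6s} {getattr(truth, name):8.3f} {getattr(fit.best, name):8.3f}")
print("best-ever score is non-increasing:",
      bool((fit.best_trace[1:] <= fit.best_trace[:-1]).all()))
print("-> the fitted column reproduces the deactivation slowing (p3r < 1),")
print("   the 6x conductance gain (p6r) and the steeper rectification (p8r).")
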