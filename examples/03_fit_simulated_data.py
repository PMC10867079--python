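"""Fit the model to simulated data by quantile chi-square.

Simulates 500 trials per condition from known parameters, bins the
data into six correct RT bins plus one error bin per condition, and
recovers the parameters by multistart Nelder-Mead on the
simulation-based chi-square objective (common random numbers make the
objective deterministic).
"""

from rdmc import FitConfig, fit, simulate_dataset
from rdmc.fitting import PARAM_ORDER
from rdmc.presets import get_preset

truth = get_preset("table3-row1")
data = simulate_dataset(truth, n_per_condition=500, seed=3)

config = FitConfig(n_sim=2000, dt=0.001, restarts=3, seed=3, max_evals=200)
result = fit(data, config, start=truth)  # starts jittered within +/-10%

print(f"{'parameter':>10} {'true':>9} {'recovered':>10}")
for key in PARAM_ORDER:
    print(f"{key:>10} {getattr(truth, key):>9.3f} "
          f"{getattr(result.params, key):>10.3f}")
print(f"\nchi-square at optimum: {result.chi2:.2f} over 14 bins "
      "(6 correct + 1 error per condition)")
print("Well-identified parameters (boundary separation, controlled drift, "
      "non-decision time) land close to truth even at 500 trials/condition; "
      "the attention parameters need more data for tight estimates.")
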