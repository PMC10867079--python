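"""The original pulse-function model as a reference.

The original conflict diffusion model describes expected automatic
evidence with a rescaled gamma pulse A*exp(-t/tau)*(t*e/((a-1)tau))^(a-1)
whose drift (its derivative) changes sign mid-trial: early distractor
evidence is later withdrawn.  Its delta-plot slope is controlled by the
pulse scale tau; a fast pulse (tau = 30 ms) yields a negative-going
delta plot.
"""

from rdmc import dmc_delta_demo, dmc_pulse_expectation
from rdmc.presets import DMC_PRESETS

p = DMC_PRESETS["dmc-fig2"]
peak_t = (p.alpha - 1) * p.tau
print(f"pulse: amplitude A = {p.A}, scale tau = {p.tau} ms, "
      f"shape alpha = {p.alpha}")
print(f"expected automatic evidence peaks at t = {peak_t:.0f} ms with "
      f"value {dmc_pulse_expectation(peak_t, p):.1f} (= A exactly)\n")

res = dmc_delta_demo(taus=(30.0, 60.0, 90.0), n=4000, seed=1)
for tau, v in res.items():
    print(f"tau = {tau:3.0f} ms: delta-plot slope = {v['slope']:+.4f}")
print("\nSlope rises with tau: slow pulses prolong distractor influence "
      "and the congruency effect keeps growing with RT, while the fast "
      "tau=30 pulse withdraws its evidence early enough to produce a "
      "negative-going delta plot.")
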