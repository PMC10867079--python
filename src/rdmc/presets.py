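"""Bundled parameter presets for the demonstration simulations.

Three families of RDMC presets plus one DMC demo configuration:

* ``table3-*`` — the three delta-plot demonstrations varying the
  congruent attention shift rate k_c in {2, 10, 20} (negative-going to
  steep positive-going delta plots);
* ``table4-*`` — group-level best fits to the benchmark Simon and
  flanker data sets (and the means of the individual fits);
* ``table5-*`` — the negative-congruency simulations, rows a–d varying
  the automatic base drift d_a and rows e–h the incongruent shift rate
  k_i;
* ``dmc-fig2`` — the reference pulse-function model demo (ms units).
"""

from __future__ import annotations

from .model_core import DMCParameters, RDMCParameters

__all__ = ["RDMC_PRESETS", "DMC_PRESETS", "get_preset", "preset_names"]

_T3 = dict(A0=0.8, k_i=30.0, d_a=0.4, d_c=0.6, a=0.094, Ter=300.0, st=0.0)

_T5 = dict(A0=0.8, k_c=2.0, d_c=0.6, a=0.094, Ter=300.0, st=0.0)

RDMC_PRESETS: dict = {
    # delta-plot demonstrations: k_c in {2, 10, 20}
    "table3-row1": RDMCParameters(k_c=2.0, **_T3),
    "table3-row2": RDMCParameters(k_c=10.0, **_T3),
    "table3-row3": RDMCParameters(k_c=20.0, **_T3),
    # group-level best fits to the benchmark Simon / flanker data
    "table4-simon-group": RDMCParameters(
        A0=0.840, k_c=0.542, k_i=25.654, d_a=0.347, d_c=0.477,
        a=0.089, Ter=279.666, st=103.512),
    "table4-flanker-group": RDMCParameters(
        A0=0.789, k_c=42.477, k_i=93.039, d_a=0.822, d_c=0.373,
        a=0.081, Ter=312.476, st=94.832),
    "table4-simon-individual": RDMCParameters(
        A0=0.853, k_c=3.945, k_i=29.382, d_a=0.372, d_c=0.521,
        a=0.092, Ter=284.166, st=84.517),
    "table4-flanker-individual": RDMCParameters(
        A0=0.799, k_c=40.265, k_i=93.772, d_a=0.773, d_c=0.406,
        a=0.086, Ter=311.823, st=99.168),
    # negative-congruency simulations: rows a-d vary d_a, e-h vary k_i
    "table5-a": RDMCParameters(k_i=30.0, d_a=0.5, **_T5),
    "table5-b": RDMCParameters(k_i=30.0, d_a=0.4, **_T5),
    "table5-c": RDMCParameters(k_i=30.0, d_a=0.35, **_T5),
    "table5-d": RDMCParameters(k_i=30.0, d_a=0.3, **_T5),
    "table5-e": RDMCParameters(k_i=30.0, d_a=0.4, **_T5),
    "table5-f": RDMCParameters(k_i=40.0, d_a=0.4, **_T5),
    "table5-g": RDMCParameters(k_i=50.0, d_a=0.4, **_T5),
    "table5-h": RDMCParameters(k_i=60.0, d_a=0.4, **_T5),
}

DMC_PRESETS: dict = {
    # pulse amplitude 20, gamma shape 2, controlled drift 0.7/ms,
    # boundary 100, diffusion scale 3, non-decision 310 +/- 40 ms
    "dmc-fig2": DMCParameters(A=20.0, tau=30.0, alpha=2.0, v_c=0.7,
                              a=100.0, sigma=3.0, Ter=310.0, st=80.0),
}


def preset_names() -> list:
    return sorted(RDMC_PRESETS) + sorted(DMC_PRESETS)


def get_preset(name: str):
    """Look up a preset by name; raises with the available names."""
    if name in RDMC_PRESETS:
        return RDMC_PRESETS[name]
    if name in DMC_PRESETS:
        return DMC_PRESETS[name]
    raise KeyError(
        f"unknown preset {name!r}; available: {', '.join(preset_names())}")
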