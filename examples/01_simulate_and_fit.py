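"""Simulate a tonometry run with the forward allosteric model and refit it.

Builds a whole-blood-like parameter set (P50 28.8 mmHg at 36 degC / pH 7.36,
n50 2.76), generates a 12-step equilibration series with 1% saturation noise,
and recovers P50/n50 by Hill-plot regression in the 30-70% window.
"""

import math

from molehb import AllostericParams, Conditions, NoiseModel, fit_hill, generate_oec

params = AllostericParams(
    logp50_ref=math.log10(28.8),
    hill_n=2.76,
    bohr_phi=-0.78,
    k_cl=0.0,
    dpg_shift=0.0,
    dh_corr=-8.3,
    ref_conditions=Conditions(temperature_c=36.0, ph=7.36),
)
grid = [5, 22, 24, 26, 28, 30, 32, 34, 36, 38, 40, 60]
dataset = generate_oec(params, params.ref_conditions, grid,
                       NoiseModel(saturation_sd=0.01, seed=42), label="demo blood")

fit = fit_hill(dataset)
print(f"true P50 = 28.80 mmHg, n50 = 2.76")
print(f"fit  P50 = {fit.p50:.2f} mmHg, n50 = {fit.n50:.2f} "
      f"(r2 = {fit.r2:.4f}, {fit.n_points_used} steps in window)")
print("The refit P50 lands within a few percent of truth despite the added")
print("saturation noise; n50 ~ 2.8 is normal tetrameric cooperativity.")
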