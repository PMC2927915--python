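"""Heterotropic linkage coefficients from paired P50 measurements.

Uses the shipped whole-blood measurements: P50/pH at PCO2 = 38 mmHg vs
CO2-free gives the CO2 Bohr slope, which then standardises P50 to pH 7.4 so
species can be compared at a common pH.
"""

from molehb import co2_bohr_coefficient, dpg_effect, ph_correct_p50

# eastern mole whole blood: (pH, P50 mmHg) at PCO2 38 mmHg and CO2-free
eastern = co2_bohr_coefficient([(7.36, 28.8), (7.76, 14.1)])
print(f"eastern mole CO2 Bohr coefficient: {eastern.value:.2f}")

# coast mole: same derivation, then standardise its P50 to pH 7.4
coast = co2_bohr_coefficient([(7.58, 17.7), (8.48, 6.1)])
p50_74 = ph_correct_p50(17.7, 7.58, 7.40, coast)
print(f"coast mole CO2 Bohr coefficient:   {coast.value:.2f}")
print(f"coast blood P50 corrected to pH 7.4: {p50_74:.1f} mmHg")

# DPG effect: paired P50 with/without saturating DPG (purified Hb style)
sensitive = dpg_effect(10.05, 18.3)
insensitive = dpg_effect(14.8, 15.5)
print(f"DPG shift, responsive Hb:   {sensitive.value:.2f} log units")
print(f"DPG shift, unresponsive Hb: {insensitive.value:.2f} log units")
print("A Bohr slope near -0.78 is unusually steep for a mammal (typical range")
print("-0.39 to -0.62); a DPG shift near zero marks a DPG-insensitive Hb.")
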