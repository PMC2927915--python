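# Demo generator configuration: three whole-blood parameter sets whose
# reference P50/pH, CO2 Bohr slope, cooperativity and corrected oxygenation
# enthalpy mirror the published mole whole-blood characteristics.
seed: 20260921
noise_sd: 0.01
po2_grid: [2, 5, 8, 11, 14, 17, 20, 24, 28, 34, 45, 60]
species:
  eastern_mole:
    p50_ref_mmHg: 28.8
    hill_n: 2.76
    bohr_phi: -0.78
    k_cl: 0.0
    dpg_shift: 0.0
    dh_corr_kJ_per_mol: -8.3
    ref_temperature_C: 36.0
    ref_ph: 7.36
  coast_mole:
    p50_ref_mmHg: 17.7
    hill_n: 2.84
    bohr_phi: -0.52
    k_cl: 0.0
    dpg_shift: 0.0
    dh_corr_kJ_per_mol: -1.0
    ref_temperature_C: 36.0
    ref_ph: 7.58
  star_nosed_mole:
    p50_ref_mmHg: 22.5
    hill_n: 2.76
    bohr_phi: -0.40
    k_cl: 0.0
    dpg_shift: 0.0
    dh_corr_kJ_per_mol: -29.9
    ref_temperature_C: 36.0
    ref_ph: 7.56
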