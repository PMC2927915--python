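species,ph_pco2_38,p50_36C_mmHg,n50_36C,ph_co2_free,p50_co2_free_mmHg,n50_co2_free,p50_32C_mmHg,p50_40C_mmHg
eastern_mole,7.36,28.8,2.76,7.76,14.1,2.54,25.3,31.0
coast_mole,7.58,17.7,2.84,8.48,6.1,2.44,16.9,19.3
star_nosed_mole,7.56,22.5,2.76,8.61,8.0,2.86,17.3,26.6
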