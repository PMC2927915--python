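species,component,p50_stripped_37C_mmHg,dlogp50_dlogcl,dlogp50_dpg,dlogp50_dph_37C_cl,dh_kJ_per_mol
eastern_mole,Hb_I,13.8,0.21,0.02,-0.51,-13.7
eastern_mole,Hb_II,14.8,0.25,0.02,-0.52,-10.3
coast_mole,Hb_I,5.3,0.31,0.26,-0.54,-9.7
coast_mole,Hb_II,5.1,0.33,0.23,-0.59,-7.6
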