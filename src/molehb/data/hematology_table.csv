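variable,units,group,mean,se,n
hematocrit,%,eastern_mole,56.4,1.3,7
hematocrit,%,coast_mole,46.8,2.0,11
hemoglobin,g/dL,eastern_mole,19.2,0.7,7
hemoglobin,g/dL,coast_mole,17.4,0.8,11
rbc,10^6/mm^3,eastern_mole,12.58,0.32,3
rbc,10^6/mm^3,coast_mole,10.48,0,1
mcv,fL,eastern_mole,46.0,1.3,3
mcv,fL,coast_mole,42.6,0,1
mch,pg,eastern_mole,15.3,0.6,3
mch,pg,coast_mole,13.5,0,1
mchc,g/L,eastern_mole,333,7,3
mchc,g/L,coast_mole,318,0,1
dpg,mM/L RBC,eastern_mole,0.45,0.06,4
dpg,mM/L RBC,coast_mole,7.09,0.20,3
myoglobin_heart,mg/g,eastern_mole,8.34,0.38,6
myoglobin_heart,mg/g,coast_mole,9.24,0.28,7
myoglobin_forelimb,mg/g,eastern_mole,10.98,0.64,6
myoglobin_forelimb,mg/g,coast_mole,12.10,0.25,10
myoglobin_hindlimb,mg/g,eastern_mole,8.56,0.21,6
myoglobin_hindlimb,mg/g,coast_mole,10.61,0.56,10
buffering_forelimb,Slykes,eastern_mole,43.86,3.29,6
buffering_forelimb,Slykes,coast_mole,37.33,2.10,10
buffering_hindlimb,Slykes,eastern_mole,44.99,5.54,6
buffering_hindlimb,Slykes,coast_mole,38.94,1.77,10
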