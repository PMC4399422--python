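species,wavelength_nm,epsilon_M_cm,solvent
crocin,443,13726,DMSO
hypochlorite,292,350,10 mmol/L NaOH
TNB,412,13600,50 mmol/L potassium phosphate pH 6.6
H2O2,230,80,water
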