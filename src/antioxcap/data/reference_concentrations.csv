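solute,uremic_mmol_L,physiological_mmol_L
L-arginine,0.230,0.140
creatinine,0.880,0.120
p-cresol,0.280,0.021
hippuric acid,1.700,0.028
methylguanidine,0.091,0.006
phenol,0.110,0.015
L-tyrosine,0.110,0.027
urea,33.000,6.700
uric acid,0.600,0.420
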