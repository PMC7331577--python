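variable,power,coefficient
age_years,1,0.0694
phe_um,1,0.3399
phe_um,2,-0.00188154
gln_um,1,-0.0133
gln_um,2,0.00002244
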