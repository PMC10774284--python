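species,D_aqueous_um2_per_h,source
GLC,2.4e6,aqueous glucose diffusivity ~6.7e-6 cm2/s at 37 C
LAC,3.6e6,aqueous lactate diffusivity ~1.0e-5 cm2/s
GLN,2.7e6,aqueous glutamine diffusivity ~7.6e-6 cm2/s
GLU,2.7e6,aqueous glutamate diffusivity ~7.6e-6 cm2/s
ALA,3.3e6,aqueous alanine diffusivity ~9.1e-6 cm2/s
SER,3.2e6,aqueous serine diffusivity ~8.8e-6 cm2/s
NH4,7.1e6,aqueous ammonium diffusivity ~2.0e-5 cm2/s
CO2,6.8e6,aqueous carbon dioxide diffusivity ~1.9e-5 cm2/s
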