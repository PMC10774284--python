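id,compartment,initial_mM,description
GLC,extracellular,25.0,glucose (bulk medium)
LAC,extracellular,0.0,lactate (bulk medium)
GLN,extracellular,4.0,glutamine (bulk medium)
GLU,extracellular,0.1,glutamate (bulk medium)
ALA,extracellular,0.1,alanine (bulk medium)
SER,extracellular,0.4,serine (bulk medium)
NH4,extracellular,0.0,ammonium (bulk medium)
CO2,extracellular,1.2,dissolved carbon dioxide / bicarbonate pool
G6P,intracellular,2.0,glucose 6-phosphate
F6P,intracellular,1.0,fructose 6-phosphate
FBP,intracellular,1.0,fructose 1:6-bisphosphate
GAP,intracellular,1.0,glyceraldehyde 3-phosphate
PG3,intracellular,1.0,3-phosphoglycerate
PEP,intracellular,1.0,phosphoenolpyruvate
PYR,intracellular,2.0,pyruvate
LACi,intracellular,2.0,intracellular lactate
ACCOA,intracellular,0.5,acetyl-CoA
CIT,intracellular,1.0,citrate
AKG,intracellular,1.0,alpha-ketoglutarate
SUC,intracellular,1.0,succinate
FUM,intracellular,0.5,fumarate
MAL,intracellular,1.0,malate
OAA,intracellular,0.2,oxaloacetate
R5P,intracellular,0.5,ribose 5-phosphate (lumped pentose pool)
GLNi,intracellular,2.0,intracellular glutamine
GLUi,intracellular,4.0,intracellular glutamate
ALAi,intracellular,1.0,intracellular alanine
ASPi,intracellular,1.0,intracellular aspartate
SERi,intracellular,4.0,intracellular serine
GLYi,intracellular,1.0,intracellular glycine
NH4i,intracellular,0.5,intracellular ammonium
BIOM,intracellular,0.0,biomass (accumulated precursor drain)
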