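reaction_id,equation,reversible,rate_law,params_json,description
HK,1 GLC -> 1 G6P,False,mm,"{""vmax"": 300.0, ""km"": {""GLC"": 8.0}, ""inhibitors"": {""G6P"": 3.0}}",glucose uptake and phosphorylation (hexokinase; transport lumped)
PGI,1 G6P -> 1 F6P,False,mm,"{""vmax"": 250, ""km"": {""G6P"": 2.0}, ""inhibitors"": {""F6P"": 3.0}}",phosphoglucose isomerase
PFK,1 F6P -> 1 FBP,False,mm,"{""vmax"": 280, ""km"": {""F6P"": 1.5}, ""inhibitors"": {""FBP"": 3.0}}",phosphofructokinase
ALD,1 FBP -> 2 GAP,False,mm,"{""vmax"": 280, ""km"": {""FBP"": 1.5}, ""inhibitors"": {""GAP"": 3.0}}",aldolase (triose isomerase lumped)
GAPDH,1 GAP -> 1 PG3,False,mm,"{""vmax"": 500, ""km"": {""GAP"": 1.5}, ""inhibitors"": {""PG3"": 3.0}}",glyceraldehyde-3-phosphate dehydrogenase (lower glycolysis lumped)
ENO,1 PG3 -> 1 PEP,False,mm,"{""vmax"": 450, ""km"": {""PG3"": 1.5}, ""inhibitors"": {""PEP"": 3.0}}",enolase (phosphoglycerate mutase lumped)
PK,1 PEP -> 1 PYR,False,mm,"{""vmax"": 450, ""km"": {""PEP"": 1.5}, ""inhibitors"": {""PYR"": 5.0}}",pyruvate kinase
LDHf,1 PYR -> 1 LACi,True,mm,"{""vmax"": 500, ""km"": {""PYR"": 2.0}, ""inhibitors"": {""LACi"": 30.0}}",lactate dehydrogenase forward
LDHr,1 LACi -> 1 PYR,True,mm,"{""vmax"": 60, ""km"": {""LACi"": 8.0}}",lactate dehydrogenase reverse
PPPox,1 G6P -> 1 R5P + 1 CO2,False,mm,"{""vmax"": 60, ""km"": {""G6P"": 2.0}, ""inhibitors"": {""R5P"": 1.0}}",pentose phosphate pathway oxidative branch (lumped)
PPPnonox,3 R5P -> 2 F6P + 1 GAP,False,mm,"{""vmax"": 25, ""km"": {""R5P"": 0.5}}",pentose phosphate pathway non-oxidative branch (lumped)
PDH,1 PYR -> 1 ACCOA + 1 CO2,False,mm,"{""vmax"": 100, ""km"": {""PYR"": 1.5}, ""inhibitors"": {""ACCOA"": 1.0}}",pyruvate dehydrogenase
CS,1 ACCOA + 1 OAA -> 1 CIT,False,mm,"{""vmax"": 100, ""km"": {""ACCOA"": 0.2, ""OAA"": 0.1}, ""inhibitors"": {""CIT"": 5.0}}",citrate synthase
IDH,1 CIT -> 1 AKG + 1 CO2,False,mm,"{""vmax"": 120, ""km"": {""CIT"": 1.0}}",isocitrate dehydrogenase (aconitase lumped)
AKGDH,1 AKG -> 1 SUC + 1 CO2,False,mm,"{""vmax"": 150, ""km"": {""AKG"": 1.5}}",alpha-ketoglutarate dehydrogenase (succinyl-CoA lumped)
SDH,1 SUC -> 1 FUM,False,mm,"{""vmax"": 150, ""km"": {""SUC"": 1.0}}",succinate dehydrogenase
FUMase,1 FUM -> 1 MAL,False,mm,"{""vmax"": 200, ""km"": {""FUM"": 0.8}}",fumarase
MDH,1 MAL -> 1 OAA,False,mm,"{""vmax"": 160, ""km"": {""MAL"": 1.0}, ""inhibitors"": {""OAA"": 0.5}}",malate dehydrogenase
PC,1 PYR + 1 CO2 -> 1 OAA,False,mm,"{""vmax"": 15, ""km"": {""PYR"": 1.5, ""CO2"": 1.0}, ""inhibitors"": {""OAA"": 0.3}}",pyruvate carboxylase (anaplerosis)
GLNSf,1 GLUi + 1 NH4i -> 1 GLNi,True,mm,"{""vmax"": 8.0, ""km"": {""GLUi"": 3.0, ""NH4i"": 1.0}, ""inhibitors"": {""GLNi"": 5.0}}",glutamine synthetase forward
GLNSr,1 GLNi -> 1 GLUi + 1 NH4i,True,mm,"{""vmax"": 20.0, ""km"": {""GLNi"": 5.0}}",glutaminase / glutamine synthetase reverse
GLDHf,1 GLUi -> 1 AKG + 1 NH4i,True,mm,"{""vmax"": 40.0, ""km"": {""GLUi"": 4.0}}",glutamate dehydrogenase forward (deamination)
GLDHr,1 AKG + 1 NH4i -> 1 GLUi,True,mm,"{""vmax"": 10.0, ""km"": {""AKG"": 2.0, ""NH4i"": 2.0}}",glutamate dehydrogenase reverse (amination)
ASTA,1 GLUi + 1 OAA -> 1 AKG + 1 ASPi,False,mm,"{""vmax"": 25.0, ""km"": {""GLUi"": 3.0, ""OAA"": 0.1}, ""inhibitors"": {""ASPi"": 2.0}}",aspartate transaminase
ALATAf,1 GLUi + 1 PYR -> 1 AKG + 1 ALAi,True,mm,"{""vmax"": 25.0, ""km"": {""GLUi"": 3.0, ""PYR"": 1.0}, ""inhibitors"": {""ALAi"": 3.0}}",alanine transaminase forward
ALATAr,1 AKG + 1 ALAi -> 1 GLUi + 1 PYR,True,mm,"{""vmax"": 10.0, ""km"": {""AKG"": 2.0, ""ALAi"": 2.0}}",alanine transaminase reverse
SERS,1 PG3 + 1 GLUi -> 1 SERi + 1 AKG,False,mm,"{""vmax"": 25.0, ""km"": {""PG3"": 0.5, ""GLUi"": 3.0}, ""inhibitors"": {""SERi"": 5.0}}",serine synthesis from 3-phosphoglycerate (lumped)
SAL,1 SERi -> 1 PYR + 1 NH4i,False,mm,"{""vmax"": 25.0, ""km"": {""SERi"": 2.0}}",serine ammonia-lyase (serine consumption)
SHMT,1 SERi -> 1 GLYi,False,mm,"{""vmax"": 15.0, ""km"": {""SERi"": 2.0}, ""inhibitors"": {""GLYi"": 2.0}}",serine hydroxymethyltransferase (one-carbon pool lumped)
GlnT,1 GLN -> 1 GLNi,False,mm,"{""vmax"": 55.0, ""km"": {""GLN"": 2.5}, ""inhibitors"": {""GLNi"": 8.0}}",glutamine uptake
LacTf,1 LACi -> 1 LAC,True,mm,"{""vmax"": 350, ""km"": {""LACi"": 3.0}}",lactate export (monocarboxylate transporter)
LacTr,1 LAC -> 1 LACi,True,mm,"{""vmax"": 30.0, ""km"": {""LAC"": 10.0}}",lactate import (monocarboxylate transporter)
AlaTf,1 ALAi -> 1 ALA,False,mm,"{""vmax"": 30.0, ""km"": {""ALAi"": 2.0}}",alanine export
ME,1 MAL -> 1 PYR + 1 CO2,False,mm,"{""vmax"": 40.0, ""km"": {""MAL"": 1.0}}",malic enzyme (cataplerotic exit from the TCA four-carbon pool)
SerT,1 SER -> 1 SERi,False,mm,"{""vmax"": 20.0, ""km"": {""SER"": 0.3}, ""inhibitors"": {""SERi"": 8.0}}",serine uptake
GluT,1 GLUi -> 1 GLU,False,mm,"{""vmax"": 4.0, ""km"": {""GLUi"": 4.0}}",glutamate export
NH4T,1 NH4i -> 1 NH4,False,mm,"{""vmax"": 60.0, ""km"": {""NH4i"": 1.0}}",ammonium export
biomass,1 R5P + 2 ACCOA + 1 ASPi + 1 GLNi + 1 GLYi -> 1 BIOM,False,mm,"{""vmax"": 12.0, ""km"": {""R5P"": 0.1, ""ACCOA"": 0.05, ""ASPi"": 0.5, ""GLNi"": 1.0, ""GLYi"": 0.5}, ""inhibitors"": {""NH4"": 10.0, ""LAC"": 40.0}}",biomass precursor drain (growth)
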