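name	formula
glycine	C2H5NO2
alanine	C3H7NO2
serine	C3H7NO3
proline	C5H9NO2
valine	C5H11NO2
threonine	C4H9NO3
cysteine	C3H7NO2S
leucine	C6H13NO2
isoleucine	C6H13NO2
asparagine	C4H8N2O3
aspartate	C4H7NO4
glutamine	C5H10N2O3
glutamate	C5H9NO4
lysine	C6H14N2O2
methionine	C5H11NO2S
histidine	C6H9N3O2
phenylalanine	C9H11NO2
arginine	C6H14N4O2
tyrosine	C9H11NO3
tryptophan	C11H12N2O2
taurine	C2H7NO3S
hypotaurine	C2H7NO2S
carnitine	C7H15NO3
acetylcarnitine	C9H17NO4
trimethyllysine	C9H20N2O2
betaine	C5H11NO2
choline	C5H13NO
creatine	C4H9N3O2
creatinine	C4H7N3O
sarcosine	C3H7NO2
ornithine	C5H12N2O2
citrulline	C6H13N3O3
4-aminobutanoate	C4H9NO2
putrescine	C4H12N2
spermidine	C7H19N3
homarine	C7H7NO2
dimethylglycine	C4H9NO2
anserine	C10H16N4O3
oxaloacetate	C4H4O5
citrate	C6H8O7
isocitrate	C6H8O7
succinate	C4H6O4
fumarate	C4H4O4
malate	C4H6O5
2-oxoglutarate	C5H6O5
pyruvate	C3H4O3
lactate	C3H6O3
glucose	C6H12O6
glycerol	C3H8O3
glycerophosphocholine	C8H20NO6P
AMP	C10H14N5O7P
ADP	C10H15N5O10P2
ATP	C10H16N5O13P3
adenosine	C10H13N5O4
inosine	C10H12N4O5
hypoxanthine	C5H4N4O
guanine	C5H5N5O
uracil	C4H4N2O2
uridine	C9H12N2O6
NAD	C21H27N7O14P2
glutathione	C10H17N3O6S
FA 14:0 (myristic acid)	C14H28O2
FA 16:0 (palmitic acid)	C16H32O2
FA 16:1 (palmitoleic acid)	C16H30O2
FA 18:0 (stearic acid)	C18H36O2
FA 18:1 (oleic acid)	C18H34O2
FA 18:2 (linoleic acid)	C18H32O2
FA 18:3 (linolenic acid)	C18H30O2
FA 18:4 (stearidonic acid)	C18H28O2
FA 20:0 (arachidic acid)	C20H40O2
FA 20:1 (gondoic acid)	C20H38O2
FA 20:3	C20H34O2
FA 20:4 (arachidonic acid)	C20H32O2
FA 20:5 (EPA)	C20H30O2
FA 22:0 (behenic acid)	C22H44O2
FA 22:1 (cetoleic acid)	C22H42O2
FA 22:5 (DPA)	C22H34O2
FA 22:6 (DHA)	C22H32O2
FA 24:1 (nervonic acid)	C24H46O2
sphingosine	C18H37NO2
sphingosine 1-phosphate	C18H38NO5P
sphingosylphosphorylcholine	C23H49N2O5P
LPE(20:5)	C25H42NO7P
LPE(22:6)	C27H44NO7P
LPE(18:1)	C23H46NO7P
PE(16:0/22:6)	C43H74NO8P
PE(16:0/20:5)	C41H72NO8P
PC(16:0/20:5)	C44H78NO8P
PC(16:0/22:6)	C46H80NO8P
taurolipid TL(16:0)	C38H71NO5S
taurolipid TL(18:1)	C40H73NO5S
taurolipid TL(20:1)	C42H75NO5S
taurolipid TL(20:5)	C42H67NO5S
taurolipid TL(22:1)	C44H79NO5S
taurolipid TL(22:6)	C44H69NO5S
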