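# additional annotatable serum compounds forming the ORA background
2-aminobutyrate
2-hydroxybutyrate
2-hydroxyisobutyrate
2-hydroxyisovalerate
2-oxoglutarate
2-oxoisocaproate
2-oxoisovalerate
3-aminoisobutyrate
3-hydroxyisobutyrate
3-hydroxypropionate
3-methyl-2-oxovalerate
acetaldehyde
acetylalanine
acetylcarnitine
acetylglycine
adenine
adenosine
allantoin
allo-threonine
anserine
arabinose
arachidonate
ascorbate
benzoate
beta-alanine
betaine
biotin
butyrate
butyrylcarnitine
caprate
caproate
caprylate
carnitine
carnosine
chenodeoxycholate
cholesterol
choline-plasmalogen
cis-aconitate
citrulline
coenzyme-q10
creatine-phosphate
creatol
cystathionine
cysteine
cystine
cytidine
cytosine
deoxycholate
desmosterol
dihydroxyacetone
ethanol
ethylene-glycol
folate
fructose
fructose-6-phosphate
fumarylacetoacetate
galactosamine
galactose
gamma-aminobutyrate
glucitol
gluconate
glucosamine
glucose-6-phosphate
glucuronate
glyceraldehyde
glycerate
glycerophosphocholine
glycocholate
glycolate
glyoxylate
guanidinoacetate
guanine
guanosine
hippurate
histamine
homocysteine
homogentisate
homoserine
hydroxyproline
indole-3-acetate
indole-3-lactate
indoxyl-sulfate
inosine
inositol
isocitrate
isopropanol
kynurenine
lathosterol
laurate
linoleate
lithocholate
malate
maltose
mannitol
mannose
melatonin
methylhistidine-1
methylhistidine-3
methylmalonate
myo-inositol
myristate
n-acetylglucosamine
n-acetylneuraminate
nicotinamide
nicotinate
oleate
orotate
oxalate
oxaloacetate
p-cresol-sulfate
p-hydroxyphenylpyruvate
palmitate
pantothenate
phenylacetate
phenylacetylglutamine
phenylpyruvate
phosphoethanolamine
pipecolate
proline
propionate
propionylcarnitine
propylene-glycol
pyridoxine
quinolinate
riboflavin
ribose
salicylate
sarcosine
scyllo-inositol
serotonin
sialate
sorbitol
squalene
stearate
succinylacetone
sucrose
taurocholate
thiamine
thymidine
thymine
trehalose
tryptamine
uracil
urea
uric-acid
uridine
valerate
xanthine
xylitol
xylose
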