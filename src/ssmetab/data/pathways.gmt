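Valine, leucine and isoleucine biosynthesis	synthetic KEGG-like catalog	valine	leucine	isoleucine
Valine, leucine and isoleucine degradation	synthetic KEGG-like catalog	valine	leucine	isoleucine	isobutyrate	acetoacetate
Synthesis and degradation of ketone bodies	synthetic KEGG-like catalog	3-hydroxybutyrate	acetoacetate	acetone
Butanoate metabolism	synthetic KEGG-like catalog	3-hydroxybutyrate	acetoacetate	succinate	glutamate	pyruvate
Glycolysis / Gluconeogenesis	synthetic KEGG-like catalog	alpha-glucose	beta-glucose	lactate	pyruvate	acetate
Galactose metabolism	synthetic KEGG-like catalog	alpha-glucose	beta-glucose	glycerol
Starch and sucrose metabolism	synthetic KEGG-like catalog	alpha-glucose	beta-glucose
Propanoate metabolism	synthetic KEGG-like catalog	succinate	pyruvate	acetate	isobutyrate	lactate
Glycerophospholipid metabolism	synthetic KEGG-like catalog	choline	phosphocholine	ethanolamine	glycerol	serine
Glycosaminoglycan biosynthesis - heparan sulfate	synthetic KEGG-like catalog	beta-glucose	n-acetyl-glycoprotein
Pyruvate metabolism	synthetic KEGG-like catalog	pyruvate	lactate	acetate
Citrate cycle (TCA cycle)	synthetic KEGG-like catalog	succinate	citrate	pyruvate	fumarate
Alanine, aspartate and glutamate metabolism	synthetic KEGG-like catalog	alanine	aspartate	asparagine	glutamate	glutamine	succinate	pyruvate	fumarate
Arginine and proline metabolism	synthetic KEGG-like catalog	arginine	ornithine	glutamate	creatine	pyruvate	fumarate
Glycine, serine and threonine metabolism	synthetic KEGG-like catalog	glycine	serine	threonine	creatine	choline	pyruvate	dimethylglycine
D-Glutamine and D-glutamate metabolism	synthetic KEGG-like catalog	glutamine	glutamate
Histidine metabolism	synthetic KEGG-like catalog	histidine	glutamate	aspartate
Lysine degradation	synthetic KEGG-like catalog	lysine	acetoacetate
Cysteine and methionine metabolism	synthetic KEGG-like catalog	methionine	serine	pyruvate
Taurine and hypotaurine metabolism	synthetic KEGG-like catalog	taurine	acetate
Aminoacyl-tRNA biosynthesis	synthetic KEGG-like catalog	alanine	arginine	asparagine	aspartate	glutamate	glutamine	glycine	histidine	isoleucine	leucine	lysine	methionine	phenylalanine	serine	threonine	tryptophan	tyrosine	valine
ABC transporters	synthetic KEGG-like catalog	valine	leucine	isoleucine	lysine	histidine	glutamine	glycine	arginine	aspartate	glutamate	taurine	methionine	choline	ornithine	serine	threonine	phenylalanine
Nitrogen metabolism	synthetic KEGG-like catalog	glutamine	glutamate	histidine	glycine
Methane metabolism	synthetic KEGG-like catalog	methanol	formate	serine	trimethylamine	dimethylamine
Phenylalanine, tyrosine and tryptophan biosynthesis	synthetic KEGG-like catalog	phenylalanine	tyrosine	tryptophan
Purine metabolism	synthetic KEGG-like catalog	hypoxanthine	glutamine	glycine
Pantothenate and CoA biosynthesis	synthetic KEGG-like catalog	valine	aspartate
Thiamine metabolism	synthetic KEGG-like catalog	tyrosine	glycine
Proximal tubule bicarbonate reclamation	synthetic KEGG-like catalog	glutamine	glutamate	lactate	alpha-glucose
Glyoxylate and dicarboxylate metabolism	synthetic KEGG-like catalog	glycine	serine	formate	citrate	acetate	glutamine	glutamate
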