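Propanoate Metabolism	synthetic pathway set	Valine	Glutamate	Propionic acid	Methylmalonic acid	Succinic acid	2-Ketobutyric acid	Beta-alanine
Valine, Leucine and Isoleucine Degradation	synthetic pathway set	Valine	Leucine	Isoleucine	3-Aminoisobutyrate	3-Methyl-2-oxovaleric acid	Ketoleucine	Isovaleryl-CoA	Methylmalonic acid	Tiglyl-CoA
Ethanol Degradation	synthetic pathway set	Acetate	Ethanol	Acetaldehyde	Acetyl-CoA	NAD
Fatty Acid Biosynthesis	synthetic pathway set	Acetate	Malonyl-CoA	Palmitic acid	Acetyl-CoA	Biotin
Amino-sugar Metabolism	synthetic pathway set	Glutamine	Glutamate	Glucose	N-Acetylglucosamine	Glucosamine	UDP-glucose
Aspartate Metabolism	synthetic pathway set	Glutamate	Citrate	Aspartic acid	Asparagine	N-Acetylaspartic acid	Oxaloacetate
Seleno-Amino Acid Metabolism	synthetic pathway set	Alanine	Selenocysteine	Selenomethionine	Cystathionine
Glutathione Metabolism	synthetic pathway set	Glutamate	Glycine	Cysteine	Glutathione	5-Oxoproline
Alanine Metabolism	synthetic pathway set	Alanine	Glutamate	Pyruvic acid	2-Oxoglutarate
Glucose-Alanine Cycle	synthetic pathway set	Alanine	Glucose	Lactate	Pyruvic acid	2-Oxoglutarate
Glutamate Metabolism	synthetic pathway set	Glutamate	Glutamine	2-Oxoglutarate	GABA	N-Acetylglutamic acid	Glutathione
Pyruvate Metabolism	synthetic pathway set	Lactate	Acetate	Pyruvic acid	Oxaloacetate	Malic acid
Warburg Effect	synthetic pathway set	Lactate	Glucose	Citrate	Glutamine	Pyruvic acid	2-Oxoglutarate	Succinic acid
Gluconeogenesis	synthetic pathway set	Glucose	Lactate	Pyruvic acid	Oxaloacetate	Glucose-6-phosphate
Cysteine Metabolism	synthetic pathway set	Cysteine	Taurine	Hypotaurine	Cystathionine
Lysine Degradation	synthetic pathway set	Lysine	Saccharopine	2-Aminoadipic acid	Glutaryl-CoA
Arachidonic Acid Metabolism	synthetic pathway set	Arachidonic acid	Prostaglandin E2	Leukotriene B4	Glutathione
Malate-Aspartate Shuttle	synthetic pathway set	Glutamate	Aspartic acid	Malic acid	Oxaloacetate	2-Oxoglutarate
Urea Cycle	synthetic pathway set	Urea	Citrulline	Ornithine	Arginine	Aspartic acid	Fumaric acid
Transfer of Acetyl Groups into Mitochondria	synthetic pathway set	Citrate	Acetate	Acetyl-CoA	Oxaloacetate	Pyruvic acid
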