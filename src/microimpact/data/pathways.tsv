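pathway_id	name
ko00010	Glycolysis / Gluconeogenesis
ko00020	Citrate cycle (TCA cycle)
ko00030	Pentose phosphate pathway
ko00040	Pentose and glucuronate interconversions
ko00051	Fructose and mannose metabolism
ko00052	Galactose metabolism
ko00053	Ascorbate and aldarate metabolism
ko00500	Starch and sucrose metabolism
ko00520	Amino sugar and nucleotide sugar metabolism
ko00620	Pyruvate metabolism
ko00630	Glyoxylate and dicarboxylate metabolism
ko00640	Propanoate metabolism
ko00650	Butanoate metabolism
ko00660	C5-Branched dibasic acid metabolism
ko00562	Inositol phosphate metabolism
ko00190	Oxidative phosphorylation
ko00195	Photosynthesis
ko00680	Methane metabolism
ko00710	Carbon fixation in photosynthetic organisms
ko00720	Carbon fixation pathways in prokaryotes
ko00910	Nitrogen metabolism
ko00920	Sulfur metabolism
ko00061	Fatty acid biosynthesis
ko00062	Fatty acid elongation
ko00071	Fatty acid degradation
ko00100	Steroid biosynthesis
ko00120	Primary bile acid biosynthesis
ko00121	Secondary bile acid biosynthesis
ko00140	Steroid hormone biosynthesis
ko00561	Glycerolipid metabolism
ko00564	Glycerophospholipid metabolism
ko00565	Ether lipid metabolism
ko00590	Arachidonic acid metabolism
ko00591	Linoleic acid metabolism
ko00592	alpha-Linolenic acid metabolism
ko00600	Sphingolipid metabolism
ko00230	Purine metabolism
ko00240	Pyrimidine metabolism
ko00250	Alanine, aspartate and glutamate metabolism
ko00260	Glycine, serine and threonine metabolism
ko00270	Cysteine and methionine metabolism
ko00280	Valine, leucine and isoleucine degradation
ko00290	Valine, leucine and isoleucine biosynthesis
ko00300	Lysine biosynthesis
ko00310	Lysine degradation
ko00220	Arginine biosynthesis
ko00330	Arginine and proline metabolism
ko00340	Histidine metabolism
ko00350	Tyrosine metabolism
ko00360	Phenylalanine metabolism
ko00380	Tryptophan metabolism
ko00400	Phenylalanine, tyrosine and tryptophan biosynthesis
ko00410	beta-Alanine metabolism
ko00430	Taurine and hypotaurine metabolism
ko00440	Phosphonate and phosphinate metabolism
ko00450	Selenocompound metabolism
ko00460	Cyanoamino acid metabolism
ko00471	D-Glutamine and D-glutamate metabolism
ko00472	D-Arginine and D-ornithine metabolism
ko00473	D-Alanine metabolism
ko00480	Glutathione metabolism
ko00510	N-Glycan biosynthesis
ko00511	Other glycan degradation
ko00512	Mucin type O-glycan biosynthesis
ko00513	Various types of N-glycan biosynthesis
ko00514	Other types of O-glycan biosynthesis
ko00515	Mannose type O-glycan biosynthesis
ko00540	Lipopolysaccharide biosynthesis
ko00550	Peptidoglycan biosynthesis
ko00571	Lipoarabinomannan (LAM) biosynthesis
ko00572	Arabinogalactan biosynthesis
ko00730	Thiamine metabolism
ko00740	Riboflavin metabolism
ko00750	Vitamin B6 metabolism
ko00760	Nicotinate and nicotinamide metabolism
ko00770	Pantothenate and CoA biosynthesis
ko00780	Biotin metabolism
ko00785	Lipoic acid metabolism
ko00790	Folate biosynthesis
ko00670	One carbon pool by folate
ko00830	Retinol metabolism
ko00860	Porphyrin and chlorophyll metabolism
ko00130	Ubiquinone and other terpenoid-quinone biosynthesis
ko00900	Terpenoid backbone biosynthesis
ko00902	Monoterpenoid biosynthesis
ko00909	Sesquiterpenoid and triterpenoid biosynthesis
ko00904	Diterpenoid biosynthesis
ko00906	Carotenoid biosynthesis
ko00981	Insect hormone biosynthesis
ko01052	Type I polyketide structures
ko00522	Biosynthesis of 12-, 14- and 16-membered macrolides
ko01051	Biosynthesis of ansamycins
ko01059	Biosynthesis of enediyne antibiotics
ko01056	Biosynthesis of type II polyketide backbone
ko01057	Biosynthesis of type II polyketide products
ko00253	Tetracycline biosynthesis
ko00523	Polyketide sugar unit biosynthesis
ko01054	Nonribosomal peptide structures
ko01053	Biosynthesis of siderophore group nonribosomal peptides
ko01055	Biosynthesis of vancomycin group antibiotics
ko00940	Phenylpropanoid biosynthesis
ko00945	Stilbenoid, diarylheptanoid and gingerol biosynthesis
ko00941	Flavonoid biosynthesis
ko00901	Indole alkaloid biosynthesis
ko00403	Indole diterpene alkaloid biosynthesis
ko00950	Isoquinoline alkaloid biosynthesis
ko00960	Tropane, piperidine and pyridine alkaloid biosynthesis
ko00232	Caffeine metabolism
ko00965	Betalain biosynthesis
ko00966	Glucosinolate biosynthesis
ko00402	Benzoxazinoid biosynthesis
ko00311	Penicillin and cephalosporin biosynthesis
ko00332	Carbapenem biosynthesis
ko00261	Monobactam biosynthesis
ko00331	Clavulanic acid biosynthesis
ko00521	Streptomycin biosynthesis
ko00524	Neomycin, kanamycin and gentamicin biosynthesis
ko00525	Acarbose and validamycin biosynthesis
ko00231	Puromycin biosynthesis
ko00401	Novobiocin biosynthesis
ko00404	Staurosporine biosynthesis
ko00405	Phenazine biosynthesis
ko00333	Prodigiosin biosynthesis
ko00254	Aflatoxin biosynthesis
ko00362	Benzoate degradation
ko00627	Aminobenzoate degradation
ko00364	Fluorobenzoate degradation
ko00625	Chloroalkane and chloroalkene degradation
ko00361	Chlorocyclohexane and chlorobenzene degradation
ko00623	Toluene degradation
ko00622	Xylene degradation
ko00633	Nitrotoluene degradation
ko00642	Ethylbenzene degradation
ko00643	Styrene degradation
ko00791	Atrazine degradation
ko00930	Caprolactam degradation
ko00363	Bisphenol degradation
ko00621	Dioxin degradation
ko00626	Naphthalene degradation
ko00624	Polycyclic aromatic hydrocarbon degradation
ko00365	Furfural degradation
ko00984	Steroid degradation
ko00980	Metabolism of xenobiotics by cytochrome P450
ko00982	Drug metabolism - cytochrome P450
ko00983	Drug metabolism - other enzymes
ko02010	ABC transporters
ko02060	Phosphotransferase system (PTS)
ko03070	Bacterial secretion system
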