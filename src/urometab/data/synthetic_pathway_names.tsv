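pathway_id	pathway_name
path01	Starch and sucrose metabolism
path02	Galactose metabolism
path03	Tryptophan metabolism
path04	Histidine metabolism
path05	Glutathione metabolism
path06	Tyrosine metabolism
path07	Phenylalanine, tyrosine and tryptophan biosynthesis
path08	Fructose and mannose metabolism
path09	Arginine and proline metabolism
path10	Glycolysis / Gluconeogenesis
path11	Citrate cycle (TCA cycle)
path12	Purine metabolism
path13	Pyrimidine metabolism
path14	Fatty acid biosynthesis
path15	Glycerophospholipid metabolism
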