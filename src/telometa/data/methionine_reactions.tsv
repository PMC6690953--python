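reaction_id	substrates	products	reversible
R_MAT	methionine;ATP;H2O	S-adenosylmethionine;Pi;PPi	0
R_GNMT	S-adenosylmethionine;glycine	S-adenosylhomocysteine;sarcosine	0
R_PEMT	phosphatidylethanolamine;S-adenosylmethionine	phosphatidylcholine;S-adenosylhomocysteine	0
R_SAHH	S-adenosylhomocysteine;H2O	homocysteine;adenosine	1
R_BHMT	betaine;homocysteine	dimethylglycine;methionine	0
R_MS	homocysteine;5-methyltetrahydrofolate	methionine;tetrahydrofolate	0
R_CBS	homocysteine;serine	cystathionine;H2O	0
R_CTH	cystathionine;H2O	cysteine;2-oxobutanoate;NH3	0
R_GCL	cysteine;glutamate;ATP	gamma-glutamylcysteine;ADP;Pi	0
R_GSS	gamma-glutamylcysteine;glycine;ATP	glutathione;ADP;Pi	0
R_GGT	glutathione;tyrosine	gamma-glutamyltyrosine;cysteinylglycine	0
R_PLA2	phosphatidylcholine;H2O	lysophosphatidylcholine;fatty acid	0
R_LPCAT	lysophosphatidylcholine;acyl-CoA	phosphatidylcholine;CoA	0
R_PLD	phosphatidylcholine;H2O	choline;phosphatidate	0
R_CHDH	choline	betaine	0
R_TAT	tyrosine;2-oxoglutarate	4-hydroxyphenylpyruvate;glutamate	1
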