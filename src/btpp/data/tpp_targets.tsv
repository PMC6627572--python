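accession	protein_name	tm_control_1	tm_treatment_1	tm_control_2	tm_treatment_2	p_value
Q00341	Vigilin	47.04	50.62	46.91	47.60	0.2204
P42330	Aldo-keto reductase family 1-member C3	47.64	52.02	48.57	52.08	0.0001
G3V180	Dipeptidyl peptidase 3	52.55	55.30	53.01	56.06	0.6632
O14980	Exportin-1	47.84	49.29	49.28	51.48	0.1985
P00558	Phosphoglycerate kinase 1	53.07	53.91	53.03	54.06	0.9584
P07339	Cathepsin D	50.68	51.78	50.47	51.73	0.0045
P07814	Bifunctional glutamate/proline--tRNA ligase	43.83	46.51	42.48	46.70	0.2816
P08133	Annexin A6	52.45	53.03	52.99	55.30	0.9961
P09327	Villin-1	49.20	51.33	48.06	50.58	0.3429
P13674	Prolyl 4-hydroxylase subunit alpha-1	51.29	54.34	52.04	54.96	0.0954
P15559	NAD(P)H dehydrogenase [quinone] 1	49.21	50.48	49.08	49.30	0.8192
P30038	Delta-1-pyrroline-5-carboxylate dehydrogenase, mitochondrial	42.97	44.66	42.77	43.22	0.9284
P45954	Short/branched chain specific acyl-CoA dehydrogenase, mitochondrial	45.27	47.28	44.85	46.52	0.7475
P60709	Actin, cytoplasmic 1	44.10	48.42	41.84	45.14	0.0455
Q06210	Glutamine--fructose-6-phosphate aminotransferase [isomerizing] 1	47.31	48.12	47.14	47.55	0.9119
Q13347	Eukaryotic translation initiation factor 3 subunit I	46.89	48.21	46.64	46.91	0.6253
Q9NR45	Sialic acid synthase	53.17	53.41	53.22	54.67	0.4993
Q9Y490	Talin-1	49.93	51.85	51.75	53.92	0.1579
Q9Y696	Chloride intracellular channel protein 4	56.78	57.32	56.63	56.85	0.7306
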