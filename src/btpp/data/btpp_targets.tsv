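accession	protein_name	tm_control_1	tm_treatment_1	tm_control_2	tm_treatment_2	p_value
P08865	40S Ribosomal protein SA	45.74	47.16	45.32	49.00	0.0385
C9JC84	Fibrinogen gamma chain	44.09	45.32	44.74	47.63	0.1800
O75874	Isocitrate dehydrogenase [NADP] cytoplasmic	47.49	48.86	48.00	49.23	0.6307
P04792	Heat shock protein beta-1	45.23	49.82	47.94	51.40	0.0099
P17980	26S proteasome regulatory subunit 6A	44.67	47.01	44.18	46.65	0.1239
P30837	Aldehyde dehydrogenase X, mitochondrial	44.34	44.97	44.19	46.96	0.6788
P60953	Cell division control protein 42 homolog	46.93	47.70	47.09	51.92	0.6179
P68363	Tubulin alpha-1B chain	42.59	45.12	42.85	47.43	0.0242
Q9Y617	Phosphoserine aminotransferase	49.03	49.78	49.49	54.35	0.2253
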