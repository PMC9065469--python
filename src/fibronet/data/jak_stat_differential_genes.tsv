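gene	compound_id	fold_change	p_value	direction
PTPN11	tanshinone_IIA	2.06	0.01	up
PIK3CB	tanshinone_IIA	2.08	0.01	up
PIK3CD	oleanolic_acid	2.58	0.01	up
PIM1	tanshinone_IIA	2.21	0.01	up
AKT2	tanshinone_IIA	0.20	0.01	down
AKT2	oleanolic_acid	0.09	0.01	down
EGFR	tanshinone_IIA	2.0	0.01	up
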