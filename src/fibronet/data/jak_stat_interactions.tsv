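compound_id	target_id	measure	value_nm	source
dihydrotanshinone_I	PTPN11	IC50	3940	ChEMBL
tanshinone_I	PTPN11	IC50	2570	ChEMBL
tanshinone_IIA	PTPN11	IC50	2590	ChEMBL
ursolic_acid	PTPN2	IC50	2400	ChEMBL
dihydrotanshinone_I	PTPN6	IC50	3670	ChEMBL
tanshinone_I	PTPN6	IC50	1970	ChEMBL
tanshinone_IIA	PTPN6	IC50	2140	ChEMBL
cryptotanshinone	STAT3	IC50	4600	ChEMBL
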