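target_id	desired_modulation	citation
STAT3	inhibit_beneficial	STAT3 inhibition represses activated hepatic stellate cells and attenuates CCl4-induced liver fibrosis
AKT2	inhibit_beneficial	AKT2 inhibition reported to treat liver fibrosis
PTPN11	inhibit_beneficial	PTPN11 (SHP2) inhibitors alleviate CCl4-induced liver fibrosis
PTPN6	activate_beneficial	PTPN6 (SHP1) agonists ameliorate liver fibrosis by upregulating PTPN6
PIK3CB	inhibit_beneficial	PI3K signaling inhibition is anti-fibrotic in hepatic stellate cells
PIK3CD	inhibit_beneficial	PI3K signaling inhibition is anti-fibrotic in hepatic stellate cells
EGFR	inhibit_beneficial	EGFR inhibition attenuates hepatic fibrogenesis
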