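# JAK/STAT signaling pathway: potential target proteins of the lipophilic
# Salvia miltiorrhiza constituents (9 evidence-backed + 10 without curated
# compound-level evidence).
PTPN11
PTPN2
PTPN6
STAT3
PIK3CB
PIK3CD
PIM1
AKT2
EGFR
PIK3CA
JAK3
JAK1
JAK2
MTOR
CCND1
MCL1
CREBBP
PDGFRA
TYK2
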