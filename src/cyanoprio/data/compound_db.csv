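name,formula,reference_mz,reference
portoamide A,C74H109N13O22,,cytotoxic cyclic peptide from Phormidium sp. LEGE 05292
portoamide B,C73H107N13O21,,cytotoxic cyclic peptide from Phormidium sp. LEGE 05292
portoamide C,C62H96N12O19,,portoamide congener
minutissamide A,C51H83N13O15,,antiproliferative cyclic lipopeptide from Anabaena minutissima
pheophorbide a,C35H36N4O5,,chlorophyll a degradation product
pyropheophorbide a,C33H34N4O3,,chlorophyll a degradation product
13(2)-hydroxy-pheophorbide a,C35H36N4O6,,chlorophyll a degradation product
13(2)-hydroxy-pheophorbide a methyl ester,C36H38N4O6,,chlorophyll a degradation product
15(1)-hydroxy-lactone-pheophorbide a methyl ester,C36H38N4O7,,chlorophyll a degradation product
15(1)-hydroxy-lactone-pheophorbide a ethyl ester,C37H40N4O7,,chlorophyll a degradation product
13(2)-hydroxy-pheophytin a,C55H74N4O6,,chlorophyll a degradation product
15(1)-hydroxy-lactone-pheophytin a,C55H74N4O7,,chlorophyll a degradation product
13-methyldioxy-pheophytin a,C56H76N4O7,,ficusmicrochlorin B; chlorophyll a degradation product
leptochelin,,895.0786,halogenated cytotoxin; structure not fully elucidated (mass-only record)
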