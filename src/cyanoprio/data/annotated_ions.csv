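observed_mz,ion_note,rt_min,log2fc,annotation,formula,adduct,source_fractions
1313.6991,,7.21,25.71,portoamide C,C62H96N12O19,[M+H]+,LEGE 05292_C
1532.7887,,7.51,28.18,portoamide A,C74H109N13O22,[M+H]+,LEGE 05292_C
1502.7780,,7.74,26.34,portoamide B,C73H107N13O21,[M+H]+,LEGE 05292_C
1154.6172,,8.73,26.07,methylated minutissamide A (tentative),C52H85N13O15,[M+Na]+,LEGE 17548_C
1118.6187,,8.76,26.86,minutissamide A,C51H83N13O15,[M+H]+,LEGE 17548_C
762.5468,,12.60,27.91,,,[M+H]+,LEGE 17548_C;LEGE 17548_D;LEGE 16572_C
703.5092,,12.31,27.33,,,[M+H]+,LEGE 16572_C
895.0778,M+2 isotope partner at 897.0759,7.92,25.98,leptochelin (tentative),,,LEGE 181150_D
851.1284,M+2 isotope partner at 853.1257,7.81,17.43,leptochelin-like (tentative),,,LEGE 181150_D
1011.8493,,14.57,27.92,,,,LEGE 181150_D
655.3808,,5.73,8.27,,,[M+H]+,LEGE 15488_C
858.5795,,7.29,8.10,,,[M+H]+,LEGE 15488_C
331.2010,in-source fragment of 858.5795,7.28,8.15,,,,LEGE 15488_C
528.3863,in-source fragment of 858.5795,7.28,9.05,,,,LEGE 15488_C
1520.7861,doubly charged partner at 760.8961,7.87,5.07,portoamide-like (tentative),C73H109N13O22,[M+H]+,LEGE 15488_C
653.2971,,12.12,7.72,15(1)-hydroxy-lactone-pheophorbide a ethyl ester,C37H40N4O7,[M+H]+,LEGE 16572_D;LEGE 15546_D;LEGE XX358_D
623.2865,dimer ions at 1245.5650 and 1267.5473,11.68,7.54,13(2)-hydroxy-pheophorbide a methyl ester,C36H38N4O6,[M+H]+,LEGE 16572_D;LEGE 15546_D;LEGE XX358_D
1245.5650,[2M+H]+ of 623.2865,11.68,15.85,13(2)-hydroxy-pheophorbide a methyl ester,C36H38N4O6,[2M+H]+,LEGE 16572_D;LEGE 15546_D;LEGE XX358_D
1267.5473,[2M+Na]+ of 623.2865,11.68,11.59,13(2)-hydroxy-pheophorbide a methyl ester,C36H38N4O6,[2M+Na]+,LEGE 16572_D;LEGE 15546_D;LEGE XX358_D
639.2813,,11.88,5.99,15(1)-hydroxy-lactone-pheophorbide a methyl ester,C36H38N4O7,[M+H]+,LEGE 16572_D;LEGE 15546_D;LEGE XX358_D
593.2759,,11.77,6.99,pheophorbide a,C35H36N4O5,[M+H]+,LEGE 16502_E;JM1 Amb_E
535.2704,,12.24,4.18,pyropheophorbide a,C33H34N4O3,[M+H]+,LEGE 16502_E;JM1 Amb_E
609.2706,,11.29,3.90,13(2)-hydroxy-pheophorbide a,C35H36N4O6,[M+H]+,LEGE 16502_E;JM1 Amb_E
636.4814,,12.90,17.14,,,,LEGE 16502_E;LEGE 15546_D
903.5618,,14.41,4.58,15(1)-hydroxy-lactone-pheophytin a,C55H74N4O7,[M+H]+,all
887.5664,,14.30,3.67,13(2)-hydroxy-pheophytin a,C55H74N4O6,[M+H]+,all
917.5777,,14.70,2.16,13-methyldioxy-pheophytin a,C56H76N4O7,[M+H]+,JM1 Amb_D;JM1 Amb_E;LEGE 16502_E
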