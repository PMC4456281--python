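group	n	soluene350_a500_per_mg_mean	soluene350_a500_per_mg_se	ptca_ng_per_mg_mean	ptca_ng_per_mg_se	ahp4_ng_per_mg_mean	ahp4_ng_per_mg_se	ttca_ng_per_mg_mean	ttca_ng_per_mg_se	ahp4_over_ptca_mean	ahp4_over_ptca_se	ttca_over_ptca_mean	ttca_over_ptca_se	a650_over_a500_mean	a650_over_a500_se
DominantBlack	5	0.549	0.027	1918.0	85.1	32.8	227.0	49.9	37.6	0.0	1.5	0.0	1.0	0.275	0.008
DominantRed	8	0.247	0.021	246.0	67.3	1943.3	179.5	623.9	29.7	9.2	1.2	3.3	0.8	0.159	0.007
RecessiveRed	9	0.173	0.020	82.8	63.4	1610.8	169.2	587.6	28.0	19.6	1.1	7.7	0.7	0.132	0.006
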