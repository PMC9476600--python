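1	999	2000	GENE_A	0	+
1	2999	4000	GENE_B	0	-
1	5999	7000	GENE_C	0	+
1	7999	9000	GENE_D	0	-
2	499	1500	GENE_E	0	+
2	2499	3500	GENE_F	0	+
11	47354998	47376999	SPI1	0	+
11	47352957	47354999	MYBPC3	0	-
11	47417768	47440127	MTCH2	0	-
11	47430458	47440126	SLC39A13	0	+
11	47440747	47448508	PSMC3	0	-
11	47459307	47470730	RAPSN	0	-
11	47487489	47574792	CELF1	0	-
11	47578127	47588547	PTPMT1	0	+
11	47588452	47606114	NDUFS3	0	-
11	47608301	47610089	FAM180B	0	-
11	47679468	47713663	AGBL2	0	-
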