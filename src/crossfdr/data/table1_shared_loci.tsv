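rank	rsid	chrom	pos	closest_genes	ccfdr
1	rs2856661	11	47374998	SPI1, MYBPC3	2.59E-05
2	rs11039199	11	47379212	SPI1	9.99E-06
3	rs7105851	11	47383275	SPI1	1.94E-05
4	rs11039203	11	47384597	SPI1	2.00E-05
5	rs67116452	11	47385194	SPI1	1.41E-05
6	rs10838698	11	47385923	SPI1	3.81E-05
7	rs10838699	11	47386073	SPI1	2.46E-05
8	rs935914	11	47387599	SPI1	1.45E-05
9	rs35996350	11	47389223	SPI1	2.25E-05
10	rs4752827	11	47389676	SPI1	3.40E-05
11	rs4752987	11	47390692	SPI1	1.16E-05
12	rs10769258	11	47391039	SPI1	1.29E-05
13	rs11039212	11	47393303	SPI1	2.12E-05
14	rs7940536	11	47395240	SPI1	2.83E-05
15	rs56030824	11	47397353	SPI1	1.17E-05
16	rs55677087	11	47397714	SPI1	1.38E-05
17	rs12146565	11	47398963	SPI1	2.26E-05
18	rs11601173	11	47401058	SPI1	1.30E-05
19	rs11607981	11	47401060	SPI1	1.37E-05
20	rs7111957	11	47409212	SPI1	1.57E-05
21	rs4752990	11	47410393	SPI1	1.29E-05
22	rs4752993	11	47410951	SPI1	1.25E-05
23	rs4752994	11	47411065	SPI1	5.90E-05
24	rs10769262	11	47411581	SPI1	3.61E-05
25	rs12803525	11	47413475	SPI1	1.02E-05
26	rs12802273	11	47418306	SPI1	1.83E-05
27	rs58965622	11	47418465	SPI1	9.86E-06
28	rs7924485	11	47419129	SPI1	1.38E-05
29	rs1317164	11	47419757	MTCH2	9.46E-06
30	rs4752832	11	47423553	MTCH2	1.21E-05
31	rs11039219	11	47424400	MTCH2	1.12E-05
32	rs755554	11	47432034	SLC39A13	1.38E-05
33	rs11600581	11	47448497	PSMC3	1.07E-05
34	rs2868459	11	47454972	MTCH2	1.32E-05
35	rs7106956	11	47458765	MTCH2	1.96E-05
36	rs35705029	11	47459963	RAPSN	9.83E-06
37	rs4752845	11	47539697	CELF1	9.17E-06
38	rs34958982	11	47547046	CELF1	1.73E-05
39	rs66749409	11	47568074	CELF1	1.94E-05
40	rs12798346	11	47583121	CELF1	2.08E-05
41	rs56400411	11	47586376	CELF1, PTPMT1	1.61E-05
42	rs7945473	11	47589707	PTPMT1	1.33E-05
43	rs2030166	11	47602729	NDUFS3	1.85E-05
44	rs11605348	11	47606483	FAM180B, NDUFS3	2.65E-05
45	rs4752856	11	47648042	MTCH2	1.53E-05
46	rs4752857	11	47655752	MTCH2	2.12E-05
47	rs11039327	11	47674084	MTCH2	8.99E-06
48	rs11604825	11	47725306	AGBL2	1.55E-05
49	rs11602395	11	47726977	AGBL2	8.76E-06
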