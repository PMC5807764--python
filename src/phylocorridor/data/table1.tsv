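# Per-population sampling and diversity summaries for the 38 Eomecon
# chionantha populations (packaged worked-example fixture).
# Columns: n_cp/n_its/n_ssr = sample sizes per marker; cp_hs / its_hs =
# within-population haplotype (chlorotype/ribotype) diversity; AR = allelic
# richness; HE/HO = expected/observed heterozygosity; FIS = inbreeding
# coefficient.  NA = marker data not available for that population.
province	location	code	lat	lon	alt	n_cp	n_its	n_ssr	cp_hs	its_hs	AR	HE	HO	FIS
Gansu	Wenxian	1	32.7142	105.2310	860	9	7	9	0.2222	0.4762	3.50	0.593	0.500	0.213
Yunnan	Wenshan	2	23.3789	103.9597	2049	10	13	15	0.3556	0.7821	2.48	0.396	0.522	-0.289
Chongqing	Jinfoshan	3	29.0529	107.1999	1253	9	3	14	0	0	2.33	0.412	0.510	-0.201
Chongqing	Jinfoshan	4	28.9917	107.0978	1388	3	0	3	0	NA	1.17	0.083	0.167	-1.000
Chongqing	Chongqing	5	29.5300	108.7700	456	4	1	10	0	NA	5.83	0.689	0.666	0.092
Guizhou	Xishui	6	28.5374	106.3943	1021	10	0	15	0	NA	2.00	0.500	0.989	-0.978
Guizhou	Suiyang	7	28.2842	107.1716	1540	10	9	15	0	0	4.99	0.580	0.600	0
Guizhou	Leigongshan	8	26.3703	108.1953	1464	14	13	12	0	0.6667	6.50	0.746	0.875	-0.131
Guizhou	Fanjingshan	9	27.9153	108.6358	1323	12	6	15	0.1667	0	8.24	0.805	0.818	0.019
Hubei	Xingdoushan	10	30.0256	109.1020	828	9	0	15	0	NA	5.64	0.690	0.611	0.148
Guangxi	Lingui	11	25.5356	110.0884	321	9	18	12	0	0.5294	3.00	0.485	0.558	-0.106
Hunan	Suining	12	26.3835	110.0971	882	10	10	12	0	0	4.00	0.613	0.447	0.311
Hunan	Huitong	13	26.6144	109.8807	564	10	18	15	0	0.5294	2.16	0.510	0.989	-0.935
Hunan	Guzhang	14	28.6600	110.0824	1390	10	12	15	0.2000	0.3030	7.11	0.784	0.742	0.090
Hunan	Xiaoxi	15	28.8675	110.2579	660	10	7	14	0.5556	0	3.64	0.533	0.591	-0.068
Hunan	Sangzhi	16	29.7871	110.0918	1390	10	1	0	0	NA	NA	NA	NA	NA
Hunan	Shimen	17	30.0496	110.5237	1830	10	12	0	0	0.5455	NA	NA	NA	NA
Hunan	Yangmingshan	18	26.0932	111.9219	867	10	20	15	0	0.5263	2.82	0.429	0.555	-0.259
Hunan	Yizhang	19	24.9719	112.9421	812	10	16	14	0	0.5333	4.61	0.605	0.690	-0.106
Hunan	Daweishan	20	28.4275	114.0516	412	8	10	0	0	0.4667	NA	NA	NA	NA
Jiangxi	Dayu	21	25.4168	114.0499	520	3	6	3	0	0.6000	2.17	0.389	0.667	-0.600
Jiangxi	Jinggangshan	22	26.5175	114.0994	896	9	0	15	0.6667	NA	4.52	0.547	0.530	0.065
Jiangxi	Luxi	23	27.5613	114.1933	525	11	7	5	0	0	2.67	0.499	0.633	-0.160
Jiangxi	Xiushui	24	28.7871	114.7388	651	9	7	15	0.2222	0.5714	3.29	0.411	0.579	-0.377
Jiangxi	Guanshan	25	28.5549	114.5923	488	10	10	15	0	0.5556	5.02	0.630	0.733	-0.130
Jiangxi	Xinfeng	26	25.2429	115.1833	278	9	20	15	0	0.5263	1.50	0.250	0.500	-1.000
Jiangxi	Yihuang	27	27.3806	116.0814	500	4	9	5	0	0	1.67	0.267	0.444	-0.569
Jiangxi	Yifeng	28	26.8678	115.7725	470	10	10	5	0	0	3.17	0.457	0.500	0.016
Jiangxi	Ruijin	29	26.0231	115.8370	320	4	6	6	0	0	1.67	0.275	0.528	-0.900
Jiangxi	Shicheng	30	26.0245	116.3417	407	8	16	6	0	0.5333	3.00	0.514	0.694	-0.269
Jiangxi	Lichuan	31	27.0694	116.9326	682	10	0	15	0.5556	NA	4.30	0.572	0.646	-0.095
Jiangxi	Bijiafeng	32	27.9242	117.8781	470	6	15	11	0	0.4762	3.67	0.570	0.476	0.231
Jiangxi	Guixi	33	28.3597	117.2083	1100	8	10	9	0	0	2.33	0.347	0.375	-0.015
Jiangxi	Shangrao	34	27.9864	118.0458	997	8	4	15	0	0.5000	3.49	0.544	0.481	0.153
Jiangxi	Wuyishan	35	27.8433	117.7264	909	3	0	14	0.6667	NA	4.95	0.644	0.553	0.203
Fujian	Jiangle	36	26.5196	117.2682	699	9	0	15	0	NA	3.48	0.515	0.522	0.024
Zhejiang	Suichang	37	28.3159	119.0049	586	8	3	0	0.4286	0	NA	NA	NA	NA
Zhejiang	Qingyuan	38	27.6464	119.1687	586	7	2	0	0	0	NA	NA	NA	NA
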