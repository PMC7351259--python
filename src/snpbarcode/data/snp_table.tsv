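index	rsid	gene	genotype1	genotype2	genotype3	case1	case2	case3	control1	control2	control3
1	rs2237054	EGF	TT	TA	AA	4408	570	22	4418	569	13
2	rs5742678	IGF1	CC	CG	GG	2797	1844	359	2866	1837	297
3	rs1549593	IGF1	CC	CA	AA	2924	1753	323	2970	1771	259
4	rs6220	IGF1	AA	AG	GG	2643	1933	424	2698	1951	351
5	rs2946834	IGF1	CC	CT	TT	2295	2171	534	2336	2150	514
6	rs1568502	IGF1R	AA	AG	GG	2914	1840	246	2955	1807	238
7	IGF1R-10	IGF1R	AA	Aa	aa	3169	1545	286	3201	1582	217
8	rs2229765	IGF1R	GG	GA	AA	1523	2533	944	1429	2489	1082
9	rs8030950	IGF1R	CC	CA	AA	2737	1902	361	2745	1917	338
10	rs680	IGF2	GG	GA	AA	2538	2074	388	2451	2183	366
11	rs3741211	IGF2	TT	TC	CC	1936	2367	697	1971	2269	760
12	IGF2-05	IGF2	AA	Aa	aa	2651	1955	394	2694	1952	354
13	IGF2-06	IGF2	AA	Aa	aa	2160	2237	603	2162	2284	554
14	rs2132571	IGFBP3	GG	GA	AA	2415	2163	422	2407	2157	436
15	rs2471551	IGFBP3	GG	GC	CC	3225	1591	184	3284	1515	201
16	rs2854744	IGFBP3	AA	AC	CC	1538	2487	975	1469	2475	1056
17	rs2132572	IGFBP3	GG	GA	AA	2908	1805	287	3027	1728	245
18	rs3024496	IL10	TT	TC	CC	1218	2533	1249	1235	2549	1216
19	rs1800872	IL10	CC	CA	AA	3059	1660	281	3017	1722	261
20	rs1800890	IL10	TT	TA	AA	1703	2455	842	1701	2508	791
21	rs1554286	IL10	CC	CT	TT	3400	1431	169	3446	1410	144
22	rs1800470	TGFB1	TT	TC	CC	1850	2372	778	1914	2399	687
23	rs699947	VEGF	CC	CA	AA	1236	2511	1253	1273	2463	1264
24	rs1570360	VEGF	GG	GA	AA	2278	2214	508	2341	2132	527
25	rs2010963	VEGF	GG	GC	CC	2354	2133	513	2279	2157	564
26	rs3025039	VEGF	CC	CT	TT	3744	1160	96	3741	1174	85
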