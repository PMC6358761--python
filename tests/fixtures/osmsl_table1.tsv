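gene_name	gene_locus	chromosome	orf_bp	exon_count	length_aa	mw_kda	pi	localization
OsMSL01	LOC_Os01g11200.1	Chr1	828	3	275	31.8	8.57	Nucleus
OsMSL02	LOC_Os01g27590.1	Chr1	1131	2	376	41.08	8.6	Nucleus
OsMSL03	LOC_Os01g34400.1	Chr1	1227	3	408	46.06	9.22	Chloroplast
OsMSL04	LOC_Os01g36850.1	Chr1	1170	2	389	57.61	9.46	Peroxisome
OsMSL05	LOC_Os01g48320.1	Chr1	999	1	332	35.92	9.62	Nucleus
OsMSL06	LOC_Os01g52090.1	Chr1	969	1	322	35.76	5.54	Nucleus
OsMSL07	LOC_Os01g62410.1	Chr1	1764	7	587	64.1	8.5	Nucleus
OsMSL08	LOC_Os02g01380.1	Chr2	1113	1	370	40.5	5.33	Nucleus
OsMSL09	LOC_Os02g07800.1	Chr2	1308	2	435	46.24	4.45	Chloroplast
OsMSL10	LOC_Os02g08450.1	Chr2	1968	4	655	74.35	7.09	Chloroplast
OsMSL11	LOC_Os02g31160.1	Chr2	1125	2	374	39.55	5.17	Nucleus
OsMSL12	LOC_Os02g33610.1	Chr2	2649	18	882	97.37	8.97	Chloroplast
OsMSL13	LOC_Os02g33770.1	Chr2	1233	1	410	46.67	6.28	Nucleus
OsMSL14	LOC_Os02g35690.1	Chr2	1260	1	419	44.44	6.11	Nucleus
OsMSL15	LOC_Os02g43300.1	Chr2	1887	3	628	67.74	4.87	Nucleus
OsMSL16	LOC_Os03g44130.1	Chr3	1104	3	367	41.74	6.61	Chloroplast
OsMSL17	LOC_Os03g46350.1	Chr3	1038	2	345	42.49	11.38	Nucleus
OsMSL18	LOC_Os04g21860.1	Chr4	1254	1	417	47.15	9.1	Nucleus
OsMSL19	LOC_Os04g30890.1	Chr4	801	1	266	28.62	9.64	Nucleus
OsMSL20	LOC_Os04g36790.1	Chr4	1254	1	417	43.93	6.53	Nucleus
OsMSL21	LOC_Os04g40930.1	Chr4	1158	5	385	41.93	5.82	Nucleus
OsMSL22	LOC_Os04g45750.1	Chr4	1587	2	528	57.46	5.74	Nucleus
OsMSL23	LOC_Os04g57530.1	Chr4	1173	2	390	41.44	9.01	Nucleus
OsMSL24	LOC_Os05g03740.1	Chr5	1002	1	333	36.95	5.85	Nucleus
OsMSL25	LOC_Os05g48690.1	Chr5	1041	1	346	37.44	9.92	Nucleus
OsMSL26	LOC_Os06g32944.1	Chr6	876	3	291	32.82	8.22	Nucleus
OsMSL27	LOC_Os07g02500.1	Chr7	1104	3	367	41.74	6.61	Chloroplast
OsMSL28	LOC_Os07g10950.1	Chr7	1437	8	478	54.23	9.06	Chloroplast
OsMSL29	LOC_Os08g08130.1	Chr8	1170	2	389	44.28	6.2	Peroxisome
OsMSL30	LOC_Os08g12950.1	Chr8	1254	1	417	47.15	8.92	Nucleus
OsMSL31	LOC_Os08g37810.1	Chr8	948	1	315	35.06	7.09	Nucleus
OsMSL32	LOC_Os08g44690.1	Chr8	912	1	303	34.83	9.29	Nucleus
OsMSL33	LOC_Os09g03570.1	Chr9	1932	7	643	73.57	9.06	Chloroplast
OsMSL34	LOC_Os09g38570.1	Chr9	1011	1	336	36.34	6.58	Nucleus
OsMSL35	LOC_Os10g33030.1	Chr10	1104	3	367	41.7	6.61	Chloroplast
OsMSL36	LOC_Os10g41460.1	Chr10	1011	1	336	35.64	8.9	Nucleus
OsMSL37	LOC_Os11g06410.1	Chr11	1492	2	483	55.06	6.24	Nucleus
OsMSL38	LOC_Os11g17954.1	Chr11	1545	4	514	58.1	8.3	Nucleus
OsMSL39	LOC_Os11g38660.1	Chr11	1938	5	645	72.97	7.34	Chloroplast
OsMSL40	LOC_Os12g06640.1	Chr12	1299	1	432	48.77	6.13	Nucleus
OsMSL41	LOC_Os12g10550.1	Chr12	888	2	295	33.5	7.74	Nucleus
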