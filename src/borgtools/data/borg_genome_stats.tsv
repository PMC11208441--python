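borg	bp	status	gc_percent	tr_regions	tr_regions_per_100kbp	tr_region_length	tr_region_percent	tr_unit_count	tr_intergenic	tr_in_orf
Green	1094519	complete	33.6	76	6.94	10223	0.93	379	46	30
Cobalt	1078846	curated	31.8	41	3.80	4552	0.42	221	26	15
Amethyst	1060114	complete	34.1	65	6.13	10377	0.98	429	32	33
Amber	1041317	complete	32.7	45	4.32	6045	0.58	259	11	34
Orange	974068	complete	32.4	53	5.44	5675	0.58	246	33	20
Brown	937932	complete	32.2	51	5.44	5913	0.63	259	28	23
Ruby	922385	curated	33.5	62	6.72	6967	0.76	351	35	27
Purple	918293	complete	32.0	66	7.19	6701	0.73	326	42	24
Black	901883	complete	32.2	57	6.32	6128	0.68	289	33	24
Iris	845347	curated	31.9	35	4.14	4878	0.58	215	27	8
Sky	763094	complete	33.0	32	4.19	3889	0.51	206	21	11
Ochre	725447	complete	33.0	23	3.17	2108	0.29	92	12	11
Red	685823	complete	32.2	23	3.35	3181	0.46	173	11	12
Viridian	673463	curated	34.3	28	4.16	3110	0.46	152	15	13
Lilac	661708	complete	32.0	61	9.22	6733	1.02	299	33	28
Rose	623782	complete	32.8	20	3.21	2132	0.34	98	8	12
Emerald	613519	curated	34.0	19	3.10	3955	0.64	88	1	18
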