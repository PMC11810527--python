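sample_id	individual_id	sex	gria2_freq	gria2_cov	cdkn2a_freq	cdkn2a_cov	tet2_freq	tet2_cov	annotation
1	1	male	1.60	48420	2.04	22260	7.34	26496	
2a	2	female	1.59	24334	2.03	22716	11.80	16883	
2b	2	female	1.49	18436	2.06	29655	16.56	22792	
3	3	female	1.44	19076	1.67	43217	13.69	27572	
4	4	male	2.25	20035	2.76	17315	8.48	30640	
5	5	male	2.24	17826	2.62	21377	9.03	38823	
6	6	female	1.48	21270	1.88	14074	19.19	44816	
7a	7	male	1.50	13543	1.76	24649	10.33	24956	
7b	7	male	1.76	19994	1.91	25090	9.87	31872	
8	8	female	1.77	17805	1.99	18078	9.54	15539	
9	9	male	0.89	21703	1.34	14625	12.82	22757	presumed calf (sighting)
10	10	male	1.95	22460	1.70	21824	12.60	30447	
11	11	male	1.98	15554	2.63	14938	15.62	19611	
12	12	male	1.72	16008	1.92	21130	10.78	27109	
13	13	male	0.66	22376	1.99	25506	11.31	17658	calf of 14
14	14	female	2.66	24223	4.64	31651	5.96	18329	mother of 13
15	15	male	2.29	24402	2.25	16600	5.59	29588	
16a	16	male	2.61	24452	2.57	28260	15.34	10249	
16b	16	male	1.91	11007	2.48	65940	11.41	37026	
17	17	male	1.50	15201	2.23	36385	10.78	32444	
18	18	female	1.07	14132	1.85	44358	11.53	45768	
19	19	male	1.52	15664	2.06	37197	10.46	62287	
20	20	male	1.82	12911	2.43	33380	12.37	32636	
21a	21	male	1.96	29249	2.28	29356	11.53	50290	
21b	21	male	1.14	17822	2.38	29959	10.38	29817	
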