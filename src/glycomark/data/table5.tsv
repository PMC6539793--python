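participant	height_cm	weight_kg	bmi	age_years	hba1c_pct	albumin_ug_ul
1	162	78	29.7	54	5.8	47.3
2	156	82	33.7	67	6.2	46
3	168	84	29.8	67	5.7	47.8
4	171	77	26.6	57	5.4	49.2
5	159	83	32.8	57	5.5	53.4
6	158	75	30.0	65	6.0	46.4
7	158	64.1	25.7	64	4.9	45.9
8	163	83	31.2	61	5.1	39.8
9	158	64	25.6	64	5.2	50
10	173	67	22.4	58	5.5	40.1
11	163	72	27.1	61	5.7	48.4
12	165	91.8	33.7	55	5.3	49
13	154	59	24.9	57	5.4	49.9
14	166	70	25.4	56	5.9	43.2
15	162	85	32.4	63	5.8	49
16	164	78	29.0	55	5.0	50.2
17	172	95	32.1	64	5.1	39
18	155	72.5	29.8	68	5.6	48.2
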