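participant	height_cm	weight_kg	bmi	age_years	disease_duration_years	hba1c_pct	albumin_ug_ul
1	157	60.3	24.5	55	13	8.6	44.4
2	165	97	35.6	50	14	9.5	35.2
3	162	89.5	34.1	64	7	8.0	44
4	175	98.5	32.2	56	8	8.6	48
5	155	80.0	33.3	68	10	8.8	34.6
6	164	105	39.0	65	14	7.5	49
7	163	72	27.0	57	1	8.1	48
8	166	76	27.6	72	3	7.4	49.3
9	157	70	28.4	65	5	7.6	41.4
10	158	105.0	42	72	10	8.1	47
11	166	69	25.0	65	10	7.7	49.4
12	156	72	29.5	58	5	8.4	46.7
13	156	67	27.5	72	9	7.7	48.4
14	160	76	29.7	57	10	8.1	48.3
15	167	89	31.9	67	10	7.7	41.4
16	148	72	32.8	70	7	9.9	29.4
17	172	105	35.5	64	3	7.6	53.4
18	160	76	29.7	70	12	8.2	50.2
19	159	144	45	46	18	10.2	34.4
20	164	72.1	26.8	74	10	9.3	49
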