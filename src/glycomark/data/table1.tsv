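number	protein	sequence	site	tr_min	mz_obs	z	error_ppm	u	u_z	p	ac	sp	sn	lda_var
1	Human serum albumin	VTK*C*C*TESLVNR	K_475	14.5	543.5926	3	0.2	45	3	<0.0001	81.6	77.7	85	V24
2	Human serum albumin	RYK*AAFTEC*C*QAADK	K_162	22.5	495.9759/660.9649	4/3	0.4/0.2	12	4	<0.0001	97.4	100	95	V14
3	Human serum albumin	LK*EC*C*EKPLLEK	K_276	24.4	427.9688/570.2889/854.9281	4/3/2	0.9/0.5/1.0	19	3	<0.0001	86.8	83.3	90	V20
4	Human serum albumin	C*ASLQK*FGER	K_205	25.4	453.2191/679.3240	3/2	0.2/1.5	14	3	<0.0001	92.1	94.4	90	V22
5	Human serum albumin	LAK*TYETTLEK	K_351	25.5	486.9246/729.8828	3/2	0.2/0.0	32	3	<0.0001	84.2	77.7	90	V15
6	Human serum albumin	YK*AAFTEC*C*QAADK	K_162	26.2	608.9315/912.8924	3/2	0.0/0.8	21	3	<0.0001	86.8	100	75	V16
7	Human serum albumin	ETYGEMADC*C*AK*QEPER	K_93	28.0	745.9667	3	0.0	43	3	<0.0001	84.2	94.4	75	V27
8	Human serum albumin	YIC*ENQDSISSK*LK	K_274	29.9	616.2968	3	0.2	44	3	<0.0001	86.8	75	100	V25
9	Human serum albumin	FK*DLGEENFK	K_12	31.0	463.5581/694.8330	3/2	0.2/0.1	44	3	<0.0001	81.6	77.7	85	V17
10	Human serum albumin	TYETTLEK*C*C*AAADPHEC*YAK	K_359	31.7	670.7864/894.0452	4/3	0.1/0.7	45	4	<0.0001	79.0	66.6	90	V28
11	Human serum albumin	K*YLYEIAR	K_137	31.9	406.5524/609.3246	3/2	0.0/0.3	22	3	<0.0001	86.8	88.8	85	V18
12	Human serum albumin	K*QTALVELVK	K_525	33.1	430.9227/645.8801	3/2	0.5/0.3	46	3	<0.0001	84.2	88.8	80	V19
13	Human serum albumin	K*VPQVSTPTLVEVSR	K_414	35.5	601.3355/901.4988	3/2	0.0/0.7	18	3	<0.0001	89.5	94.4	85	V11
14	Human serum albumin	ADLAK*YIC*ENQDSISSK	K_262	36.0	701.9975	3	0.7	49	3	0.0001	86.8	100	75	V1
15	Human serum albumin	LVTDLTK*VHTEC*C*HGDLLEC*ADDR	K_240	36.1	604.6759/755.5923/1007.1200	5/4/3	1.2/0.4/0.3	43	5	<0.0001	84.2	70	100	V23
16	Human serum albumin	TC*VADESAENC*DK*SLHTLFGDK	K_64	37.4	665.5443/887.0572	4/3	1.4/2.1	34	4	<0.0001	84.2	66.6	100	V2
17	Human serum albumin	K*LVAASQAALGL	K_574	37.5	652.3774	2	0.2	56	2	0.0003	79.0	66.6	90	V12
18	Human serum albumin	AAFTEC*C*QAADK*AAC*LLPK	K_174	38.5	763.0193	3	0.7	30	3	<0.0001	84.2	66.6	100	V3
19	Human serum albumin	LVNEVTEFAK*TC*VADESAENC*DK	K_51	38.7	698.5634/931.0817	4/3	0.4/0.2	17	4	<0.0001	84.2	94.4	75	V4
20	Human serum albumin	AAC*LLPK*LDELR	K_181	40.9	520.9491/780.9191	3/2	0.8/0.1	40	3	<0.0001	86.8	88.8	85	V21
21	Human serum albumin	SLHTLFGDK*LC*TVATLR	K_73	42.5	524.2790/698.7018	4/3	1.0/0.3	41	3	<0.0001	81.6	83.3	80	V13
22	Human serum albumin	EFNAETFTFHADIC*TLSEK*ER	K_519	42.9	677.5613/903.0777	4/3	0.7/0.8	67	4	0.0010	73.7	55.5	90	V26
23	Human serum albumin	TC*VADESAENC*DK*SLHTLFGDKLC*TVATLR	K_64	43.1	894.1641	4	5.0	51	4	0.0001	81.6	72.2	90	V29
24	Human serum albumin	EQLK*AVM*DDFAAFVEK	K_545	43.9	673.6598	3	0.3	68	3	0.0011	76.3	88.8	65	V7
25	Human serum albumin	VFDEFK*PLVEEPQNLIK	K_378	45.8	736.3884	3	0.4	80	3	0.0036	76.3	72.2	80	V5
26	Human serum albumin	AEFAEVSK*LVTDLTK	K_233	48.5	604.9884	3	0.8	79	3	0.0033	79.0	88.8	70	V6
27	Human serum albumin	RHPYFYAPELLFFAK*	K_159	50.1	516.0182	4	0.4	86	4	0.0063	73.7	44.4	100	V30
28	Alpha-2-macroglobulin	LVDGK*GVPIPNK	K_375	28.5	466.9332	3	0.2	33	3	<0.0001	86.8	94.4	80	V32
29	Alpha-2-macroglobulin	ALLAYAFALAGNQDK*R	K_1162	46.2	628.6674	3	0.0	77	3	0.0027	76.3	66.6	85	V10
30	Apolipoprotein A1	LAEYHAK*ATEHLSTLSEK	K_219	28.5	548.2794	4	0.5	80	4	0.0036	76.3	94.4	60	V39
31	Ceruloplasmin precursor	VTFHNK*GAYPLSIEPIGVR	K_468	39.9	565.8053	4	0.0	57	4	<0.0001	84.2	70	100	V40
32	Complement C4-A	RC*SVFYGAPSK*SR	K_1575	39.0	838.9029	2	5.0	27	2	<0.0001	84.2	72.2	95	V42
33	FLJ00385 protein	VSNK*ALPAPIEK	K_319	26.6	476.9368/714.9006	3/2	0.0/1.0	30	3	<0.0001	86.8	75	100	V38
34	Ig kappa chain C region	VQWK*VDNALQSGNSQESVTEQDSK	K_41	34.3	947.1123	3	0.6	51	3	0.0002	81.6	94.4	70	V8
35	Ig kappa chain C region	DSTYSLSSTLTLSK*ADYEK	K_75	38.7	757.6970	3	0.5	35	3	<0.0001	86.8	88.8	85	V9
36	Serotransferrin	GDVAFVK*HQTVPQNTGGK	K_553	25.7	512.0137	4	0.6	37	4	<0.0001	86.8	94.4	80	V31
37	Serotransferrin	DDTVC*LAK*LHDR	K_659	29.0	401.9458/535.5914	4/3	0.5/0.2	25	4	<0.0001	84.2	94.4	75	V36
38	Serotransferrin	KPVDEYK*DC*HLAQVPSHTVVAR	K_258	30.2	543.0768/678.5909/904.4496	5/4/3	2.4/2.2/4.8	34	5	<0.0001	86.8	88.8	85	V37
39	Serotransferrin	SK*EFQLFSSPHGK	K_299	34.3	414.2098/551.9418	4/3	2.1/1.4	42	3	<0.0001	81.6	77.7	85	V34
40	Serotransferrin	DLLFK*DSAHGFLK	K_315	40.3	413.9693/551.6227	4/3	0.2/0.5	47	4	0.0001	81.6	83.3	80	V35
41	Serotransferrin	DGAGDVAFVK*HSTIFENLANK	K_225	41.6	599.5509/799.0649	4/3	0.8/0.5	53	3	0.0002	84.2	94.4	75	V33
42	Vitamin D-binding protein precursor	TSALSAK*SC*ESNSPFPVHPGTAEC*C*TK	K_94	32.3	772.0957	4	1.3	39	4	<0.0001	86.8	83.3	90	V41
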