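protein	site	marker_peptide	peptide_number	half_life_days
Alpha-2-macroglobulin	K_1162	ALLAYAFALAGNQDK*R	29	1-2
Complement C4-A	K_1575	RC*SVFYGAPSK*SR	32	2-3
Vitamin D-binding protein precursor	K_94	TSALSAK*SC*ESNSPFPVHPGTAEC*C*TK	42	2.5-3
Ceruloplasmin	K_468	VTFHNK*GAYPLSIEPIGVR	31	5.5
Apolipoprotein A1	K_219	LAEYHAK*ATEHLSTLSEK	30	5-6
Serotransferrin	K_299	SK*EFQLFSSPHGK	39	8-10
Ig kappa chain C region	K_75	DSTYSLSSTLTLSK*ADYEK	35	19-21
Human serum albumin	K_159	RHPYFYAPELLFFAK*	27	19-21
FLJ00385 protein	K_319	VSNK*ALPAPIEK	33
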