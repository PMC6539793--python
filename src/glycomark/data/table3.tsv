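model	loo_ac	loo_sp	loo_sn	sub_ac	sub_sp	sub_sn	variables
VIF10	81.58	88.89	75	84.21	94.44	75	V6 V7 V9 V10 V12 V28 V29 V30 V32 V33 V34 V39 V40 V41 V42
VIF5_1	92.11	100	85	86.84	94.44	80	V6 V10 V12 V28 V29 V30 V33 V34 V39 V41 V42
VIF5_2	89.47	100	80	89.47	94.44	85	V7 V10 V12 V28 V29 V30 V32 V33 V34 V39 V41 V42
PCA	84.2	100	70				PC1 PC2 PC3 PC4 PC5 PC6 PC7 PC8 PC9
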