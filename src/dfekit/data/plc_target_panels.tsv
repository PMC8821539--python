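# Per-target protein-ligand panels: published least-squares statistics of
# dg_exp against DFE for each target's ligand set.  r2_excl / se_excl are
# the values after removing the two Thrombin outliers (blank elsewhere).
# slope/intercept give the per-target relationship dg_exp = slope*DFE + intercept.
target	n_ligands	cv_residue	n_runs	t_ns	r2	se	slope	intercept	r2_excl	se_excl
CDK2	16	F80	40	20	0.67	0.72	0.858	7.26
TYK2	16	M978	50	10	0.66	0.79	0.602	-0.85
P38a	34	L75	40	20	0.6	0.65	0.39	-3.33
JNK1	21	L110	27	10	0.51	0.62	0.559	-2.86
MCL1	42	L290	30	10	0.48	0.78	0.642	-1.96
PTP1B	23	R221	40	15	0.35	1.09	0.628	4.19
BACE	36	W176	40	20	0.32	0.65	0.268	-4.18
Thrombin	11	S214	50	10	0.01	0.57	0.793	0.37	0.62	0.36
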