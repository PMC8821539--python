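# Benchmark panel: 19 non-congeneric protein-protein complexes with
# published DFE values (post- and pre-correction), calibrated predictions,
# experimental binding free energies and dissociation constants.
# dg_exp = kT ln(Kd) at 310 K; energies kcal/mol; kd molar; t_ns is the
# per-run chemical time before any extension.
complex_id	dfe	dfe_err	dg_calc	dg_exp	kd	n_runs	t_ns	dfe_nc	dg_calc_nc	corrections
1EMV	-32.42	0.16	-15.65	-19.32	2.4e-14	50	40	-32.42	-15.57	none
2PTC	-36.59	0.27	-17.53	-18.75	6e-14	50	20	-35.95	-17.43	18 runs extended to 30 ns; 2 runs to 40 ns
1BVN	-34.67	0.07	-16.66	-15.65	9.2e-12	50	40	-34.67	-16.57	none
1R0R	-32.38	0.13	-15.63	-14.94	2.94e-11	50	20	-32.38	-15.55	none
1ACB	-29.38	0.2	-14.27	-13.76	2e-10	50	30	-29.38	-14.22	none
1AY7	-28.54	0.18	-13.9	-13.76	2e-10	60	40	-30.76	-14.36	13 runs with invasions removed
2UUY	-24.11	0.32	-11.9	-11.7	5.6e-9	50	20	-24.14	-11.88	4 runs extended to 30 ns
1KAC	-23.99	0.16	-11.84	-11.11	1.48e-8	50	30	-23.99	-11.82	none
3BZD	-17.73	0.23	-9.02	-9.95	9.6e-8	50	20	-17.77	-9.04	3 runs with invasions removed
2C0L	-14.56	0.15	-7.59	-9.88	1.09e-7	50	20	-15.9	-7.61	13 runs with repeated sampling removed
1KTZ	-20.78	0.05	-10.39	-9.27	2.9e-7	50	20	-20.79	-10.39	8 runs extended to 30 ns
3LVK	-17.72	0.17	-9.01	-9.25	3e-7	50	20	-16.89	-9.02	3 runs with repeated sampling removed; 11 runs extended to 30 ns; 2 runs to 40 ns
1FFW	-14.46	0.07	-7.54	-8.33	1.35e-6	50	10	-13.24	-7.03	11 runs with repeated sampling removed; 6 runs extended to 20 ns
3F1P	-20.83	0.47	-10.42	-8.3	1.4e-6	50	30	-20.31	-10.41	7 runs with repeated sampling removed; 2 runs extended to 40 ns
1US7	-17.59	0.16	-8.96	-8.28	1.46e-6	50	10	-17.59	-8.96	none
3A4S	-13.61	0.17	-7.16	-7.87	2.81e-6	50	10	-14.42	-7.55	2 runs with invasions removed; 17 runs extended 20 ns
1QA9	-20.74	0.12	-10.38	-7.16	9e-6	50	20	-20.74	-10.37	none
2OOB	-9.81	0.15	-5.44	-5.99	6e-5	50	10	-9.54	-5.5	2 runs with repeated sampling removed; 5 runs extended to 20 ns
3SGB	-18.84	0.03	-9.52	-15.24	1.79e-11	50	40	-18.84	-8.96	none
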