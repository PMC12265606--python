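# Published association statistics for the five chromosome-15 candidate
# variants nominated for Trail Making Test part B in a multigenerational
# family study (linked / top-linked family sets).  Used as *input* to the
# nomination filter and the percent-of-peak arithmetic.
variant_id	chr	bp	symbol	ea	nonea	af_linked	n_linked	beta_linked	se_linked	pval_linked	lod_drop_linked	af_top	n_top	beta_top	se_top	pval_top	lod_drop_top
rs2271159	15	80887585	CEMIP	T	G	0.305	393	-0.42	0.09	2.86e-06	3.33	0.29	115	-0.48	0.16	2.68e-03	1.43
rs4134376	15	85885026	-	G	A	0.126	393	-0.6	0.12	5.97e-07	2.2	0.23	117	-0.59	0.17	6.37e-04	1.39
rs74031103	15	88208591	NTRK3	C	A	0.011	392	0.78	0.37	3.40e-02	0.74	0.02	117	1.79	0.44	7.82e-05	2.4
15:85882445:IND	15	85882445	KLHL25	C	CTT	0.07	379	-0.83	0.16	3.60e-07	1.74	0.132	110	-0.74	0.22	1.37e-03	0.98
15:80893381:IND	15	80893381	CEMIP	A	AG	0.2	378	-0.43	0.1	1.20e-05	1.93	0.213	108	-0.72	0.17	3.52e-05	1.91
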