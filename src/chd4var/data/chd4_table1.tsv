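# Study fixture: the 36 CHD4 variants analysed in the source study of rare-disease
# patients with cardiovascular anomalies (33 missense, transcribed from the published
# predictor-score/classification table, plus one splice-donor, one in-frame duplication
# and one in-frame deletion described in the accompanying narrative).
# Columns `revel_label`, `acmg` and `comparison` carry the published per-row calls and
# are used as golden expectations in the test suite; they are never read by the pipeline.
# `heart_anomaly` flags are editorial transcriptions consistent with the published
# group counts (19/20 ATPase-motor-region vs 9/15 informative other-domain variants);
# the study does not identify which single motor-region variant lacks an anomaly, and
# this fixture assigns the "no" to p.A1178V (see docs/methods.md).
variant	type	cdna	metarnn	polyphen2	alphamissense	revel	evidence	gnomad_af	clinvar	heart_anomaly	diseases	syndrome	revel_label	acmg	comparison
p.P8S	missense	c.22C>T	0.24	0.91	0.09	0.294	PM2+PM6		LP	no	H+LVH+CAD	MMA	Undetermined	VUS	Downgraded
p.M202I	missense		0.90	0.98	1.0	0.788	PS2+PS3+PM2+PP3		VUS	yes	VSD	SIHIWES	PP3_moderate	P	Upgraded
p.P286A	missense	c.856C>G	0.16	0.02	0.05	0.239	PM2+PP2+BP4	4.09e-6	NP	yes	SA	IP_sinus_arrhythmia	BP4_supporting	VUS	First classification
p.C467Y	missense	c.4018C>T	0.99	1.0	1.0	0.968	PS2+PS3+PM2+PP3		NP	yes	TF	SIHIWES	PP3_strong	P	First classification
p.T494M	missense		0.41	0.707	0.10	0.14	PM2+BS2+BP4		VUS	no	CVD	MMA	BP4_moderate	LB	Downgraded
p.K533E	missense	c.1597A>G	0.23	0.35	0.44	0.316	PS2+PM2		VUS	yes	SA+E	IP_sinus_arrhythmia	Undetermined	LP	Upgraded
c.1686+1G>T	splice_donor	c.1686+1G>T					PM2		LP	unknown	CVD	MMA			
p.K810N	missense		0.66	1.0	1.0	0.548	PS2+PM2		NP	yes	CHD	SIHIWES	Undetermined	LP	First classification
p.S851Y	missense		0.98	0.99	1.0	0.985	PS2+PM2+PP3		P	yes	CHD	SIHIWES	PP3_strong	LP	Downgraded
p.R887W	missense		0.89	1.0	0.95	0.884	PS2+PM2+PP3		P	yes	CHD	SIHIWES	PP3_moderate	LP	Downgraded
p.M954I	missense		0.88	0.90	0.99	0.905	PS2+PM2+PP3		P	yes	CHD	SIHIWES	PP3_moderate	LP	Downgraded
p.M954V	missense		0.91	1.0	0.82	0.938	PS2+PS3+PM2+PP3		NP	yes	CHD	SIHIWES	PP3_strong	P	First classification
p.M966K	missense		0.86	0.98	0.99	0.889	PS2+PM2+PP3		LP	yes	CHD	SIHIWES	PP3_moderate	LP	Unchanged
p.R992Q	missense		0.88	1.0	0.72	0.685	PS2+PS3+PM2+PP3		CS	yes	CHD	SIHIWES	PP3_supporting	P	Upgraded
p.G1003D	missense		0.89	1.0	1.0	0.785	PS2+PS3+PM2+PP3		NP	yes	CHD	SIHIWES	PP3_moderate	P	First classification
p.L1009_V1011dup	inframe_dup						PM2		NP	yes	TF	SIHIWES			
p.C1012del	inframe_del						PM2		NP	yes	TF	SIHIWES			
p.N1020S	missense		0.94	1.0	0.73	0.855	PS2+PM2+PP3		LP	yes	CHD	SIHIWES	PP3_moderate	LP	Unchanged
p.R1068H	missense		0.91	1.0	0.97	0.933	PS2+PS3+PM2+PP3		P	yes	TF	SIHIWES	PP3_strong	P	Unchanged
p.E1094K	missense		0.93	1.0	1.0	0.958	PS2+PS3+PM2+PP3		P	yes	CHD	SIHIWES	PP3_strong	P	Unchanged
p.D1147E	missense		0.82	0.16	0.99	0.845	PS2+PM2+PP3		LP	yes	CHD	SIHIWES	PP3_moderate	LP	Unchanged
p.W1148L	missense		0.92	0.511	1.0	0.76	PS2+PM2+PP3		P	yes	CHD	SIHIWES	PP3_supporting	LP	Downgraded
p.A1178V	missense		0.55	0.06	0.91	0.462	PS2+PM2		LP	no		SIHIWES	Undetermined	LP	Unchanged
p.R1183H	missense		0.85	0.99	0.97	0.71	PS2+PM2+PP3		P/LP	yes	CHD	SIHIWES	PP3_supporting	LP	Unchanged
p.R1183C	missense		0.89	1.0	0.99	0.877	PS2+PM2+PP3		P/LP	yes	CHD	SIHIWES	PP3_moderate	LP	Unchanged
p.A1188V	missense		0.89	0.24	0.97	0.828	PS2+PM2+PP3		NP	yes	CHD	SIHIWES	PP3_moderate	LP	First classification
p.M1192R	missense		0.80	0.01	0.99	0.797	PS2+PM2+PP3		NP	yes	CHD	SIHIWES	PP3_moderate	LP	First classification
p.Y1249D	missense		0.90	0.40	1.0	0.856	PS2+PM2+PP3		LP	yes	ASD+SA	SIHIWES	PP3_moderate	LP	Unchanged
p.Y1345D	missense		0.91	1.0	1.0	0.809	PS2+PM2+PP3		NP	yes	TF	SIHIWES	PP3_moderate	LP	First classification
p.R1419H	missense		0.91	0.26	0.992	0.861	PM2+PM6+PP2+PP3		LP	yes	D	other	PP3_moderate	LP	Unchanged
p.V1608I	missense		0.07	0.01	0.07	0.171	PS2+PM2+BP4		CS	yes	CHD	SIHIWES	BP4_moderate	LP	Upgraded
p.E1646K	missense		0.26	0.455	0.15	0.459	PS2+PM2		NP	yes	CHD	SIHIWES	Undetermined	LP	First classification
p.D1659E	missense		0.08	0.00	0.09	0.321	PM2+PP2		NP	no		SIHIWES	Undetermined	VUS	First classification
p.I1741V	missense		0.58	0.25	0.66	0.5	PM2+PM6		LP	no	CVD+H	MMA	Undetermined	VUS	Downgraded
p.Y1758C	missense		0.90	0.98	0.97	0.734	PM2+PM6+PP3		CS	no	CVD+H	MMA	PP3_supporting	VUS	Unchanged
p.P1880S	missense		0.87	0.997	0.89	0.773	PM2+PM6+PP3		VUS	no	CVD+CAD	MMA	PP3_moderate	VUS	Unchanged
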