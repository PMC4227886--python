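gene	direction	rpkm_control	rpkm_treated	fold_printed	p_value	fold_consistent
RPS28	up	0.52	21.63	40.74	0.0005	False
TTLL3	up	1.09	23.57	21.41	0.028	False
CISH	up	1.97	27.94	13.99	1.38E-10	False
SCN4A	up	1.87	20.79	10.95	5.29E-21	False
BLB1	up	0.74	7.13	9.53	0.009	False
TGM2	up	0.20	1.78	8.88	0.037	False
SS1R	up	0.68	5.33	8.75	0.015	False
SERPINA4	up	8.86	78.26	8.70	1.06E-18	False
GGA.45581	up	35.97	278.79	7.64	9.82E-31	False
CCK	up	3.23	24.44	7.46	5.05E-05	False
AFP	down	38.74	0.10	0.0025	4.76E-40	False
RGS6	down	1.92	0.09	0.047	0.014	True
STAR	down	27.75	5.01	0.18	1.28E-08	True
CCKAR	down	5.57	1.01	0.18	0.013	True
KIAA0408	down	3.38	0.63	0.19	0.020	True
BCL6	down	19.86	4.26	0.21	8.27E-08	True
PDE10A	down	7.07	1.57	0.22	0.002	True
ENSGALG00000024377	down	26.06	6.18	0.23	0.044	False
NECAB1	down	7.12	1.74	0.24	0.010	True
TAGLN3	down	34.96	8.62	0.24	5.64E-06	False
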