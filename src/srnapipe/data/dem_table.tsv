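mirna	tier	direction	rpm_control	rpm_treated	fold_printed	p_value	fold_consistent
gga-miR-15b	known	up	35.3	63.9	1.8	2.27E-07	True
gga-miR-19b	known	up	263.9	451.0	1.7	5.49E-36	True
gga-miR-29b	known	up	31.5	49.0	1.6	4.71E-04	True
gga-miR-99a-5p	known	up	9.2	15.4	1.7	0.022	True
gga-miR-146b-3p	known	up	3.8	7.5	2.0	0.043	True
gga-miR-181a-3p	known	up	45.0	68.6	1.5	7.91E-05	True
gga-miR-190	known	up	96.0	162.8	1.7	1.02E-13	True
gga-miR-193a	known	up	17.9	30.8	1.7	8.78E-04	True
gga-miR-194	known	up	15.6	23.8	1.5	0.019	True
gga-miR-223	known	up	55.7	94.2	1.7	1.71E-08	True
gga-miR-455-3p	known	up	15.5	24.7	1.6	0.008	True
gga-miR-1306	known	up	0.6	3.7	6.5	0.003	False
gga-miR-1618-5p	known	up	1.1	4.2	3.7	0.011	False
gga-miR-1628	known	up	0.4	2.3	6.1	0.019	False
gga-miR-1699	known	up	1.5	5.6	3.7	0.003	True
gga-miR-1731	known	up	35.9	56.0	1.6	1.72E-04	True
gga-miR-1724	known	down	2.3	0.01	0.004	0.023	True
aca-miR-16b-5p	homolog	up	3.2	7.9	2.4	0.009	False
aca-miR-30c-3p	homolog	up	11.1	19.6	1.8	0.005	True
ahy-miR-3512	homolog	up	21.4	52.7	2.5	2.30E-11	True
bta-miR-139	homolog	up	11.8	22.4	1.9	0.001	True
ccr-miR-92a	homolog	up	21.2	43.8	2.1	3.20E-07	True
ccr-miR-99	homolog	up	1.1	3.7	3.3	0.024	False
hsa-miR-34a-3p	homolog	up	1.7	4.7	2.7	0.027	False
hsa-miR-4792	homolog	up	852.8	1356.3	1.6	3.19E-81	True
mmu-miR-6238	homolog	up	0.8	2.8	3.7	0.036	False
oan-miR-1335	homolog	up	41.0	71.8	1.8	1.84E-07	True
ola-miR-122	homolog	up	19.3	30.3	1.6	0.005	True
ppt-miR-894	homolog	up	9.5	15.9	1.7	0.022	True
tca-miR-3885-5p	homolog	up	14.3	27.1	1.9	3.19E-04	True
xtr-miR-210	homolog	up	11.8	24.3	2.0	1.60E-04	False
xtr-miR-212	homolog	up	1.7	5.1	3.0	0.013	True
ccr-miR-22b	homolog	down	12.2	5.1	0.4	0.005	True
ccr-miR-26a	homolog	down	75.8	29.4	0.4	9.45E-15	True
ccr-miR-130c	homolog	down	10.9	4.7	0.4	0.009	True
cgr-miR-425-5p	homolog	down	13.2	4.7	0.4	7.79E-04	True
ggo-let-7f	homolog	down	71.2	37.8	0.5	4.46E-08	True
ggo-miR-146a	homolog	down	34.34	11.2	0.3	4.96E-09	True
gga-m0060-3p	novel	up	0.01	1.9	186.6	0.004	False
gga-m0006-5p	novel	up	0.01	1.4	139.9	0.014	False
gga-m0072-3p	novel	up	0.8	2.8	3.7	0.036	False
gga-m0085-3p	novel	up	5.0	12.6	2.5	7.13E-04	True
gga-m0073-3p	novel	up	6.9	14.0	2.0	0.004	True
gga-m0018-5p	novel	down	1.9	0.01	0.005	0.046	True
gga-m0011-5p	novel	down	2.9	0.01	0.003	0.008	True
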