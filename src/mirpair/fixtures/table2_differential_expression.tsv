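gene	tumor_mean	normal_mean	fold_change	p_value	p_adjusted	direction
FGF9	1.66	9.08	0.18	4.27E-30	6.44E-29	down
PPP3R2	0.20	0.93	0.21	3.56E-07	8.02E-07	down
CACNG3	0.16	0.62	0.25	4.46E-04	7.32E-04	down
CACNG7	0.17	0.67	0.25	1.91E-05	3.48E-05	down
CACNA1A	3.27	12.58	0.26	2.27E-32	4.57E-31	down
CACNA1G	1.26	4.80	0.26	4.08E-16	1.79E-15	down
CACNA1F	1.68	6.25	0.27	1.60E-21	1.01E-20	down
RASGRP2	6.72	24.73	0.27	1.04E-31	1.93E-30	down
PRKCB	14.65	53.12	0.28	1.52E-41	7.31E-40	down
CACNA1I	1.91	6.56	0.29	8.80E-19	4.51E-18	down
MAPK10	9.26	28.10	0.33	8.93E-34	1.96E-32	down
MAP4K1	7.24	21.46	0.34	1.58E-26	1.74E-25	down
CACNG2	0.21	0.57	0.37	2.28E-03	3.41E-03	down
PRKACB	62.60	162.73	0.38	5.72E-40	1.97E-38	down
FGFR2	26.51	68.82	0.39	2.32E-21	1.40E-20	down
MEF2C	27.15	66.82	0.41	1.00E-41	6.02E-40	down
FOS	185.52	453.52	0.41	9.65E-31	1.66E-29	down
CACNG1	0.27	0.65	0.42	3.35E-05	5.89E-05	down
FGF10	1.70	4.06	0.42	1.85E-10	5.45E-10	down
PTPN5	0.89	2.09	0.42	7.08E-07	1.55E-06	down
DUSP1	67.66	154.53	0.44	1.02E-34	2.46E-33	down
EGF	2.83	6.34	0.45	1.71E-05	3.15E-05	down
CACNB2	26.71	59.55	0.45	1.00E-38	3.03E-37	down
IL1R2	7.02	15.61	0.45	1.00E-13	3.77E-13	down
NTRK1	1.10	2.43	0.45	3.24E-07	7.36E-07	down
CACNA1B	1.79	3.91	0.46	1.99E-06	4.14E-06	down
NTRK2	17.81	38.41	0.46	1.04E-08	2.67E-08	down
DUSP5	28.27	59.40	0.48	1.39E-22	9.28E-22	down
CACNA1H	53.11	106.08	0.50	5.22E-27	5.99E-26	down
FGFR3	36.15	70.78	0.51	1.13E-18	5.54E-18	down
MAPT	4.51	8.74	0.52	1.01E-12	3.40E-12	down
NFATC1	12.01	22.97	0.52	3.23E-17	1.50E-16	down
PDGFRA	88.47	166.61	0.53	5.08E-26	5.11E-25	down
CACNA2D3	1.56	2.91	0.53	1.46E-04	2.46E-04	down
MAPK7	21.28	38.75	0.55	6.78E-29	9.08E-28	down
FAS	28.16	50.95	0.55	2.75E-24	2.46E-23	down
CACNA1S	0.56	1.00	0.56	6.90E-03	1.00E-02	down
RASGRP1	21.77	38.90	0.56	1.20E-22	8.23E-22	down
PRKACG	0.17	0.31	0.56	1.84E-03	2.79E-03	down
RASGRP3	25.53	45.22	0.56	1.16E-20	6.81E-20	down
FGF2	10.04	17.66	0.57	2.79E-13	9.89E-13	down
FGF13	2.42	4.18	0.58	2.84E-05	5.06E-05	down
RAC2	22.11	37.39	0.59	4.70E-16	2.02E-15	down
FGF7	8.17	13.70	0.60	1.49E-08	3.69E-08	down
NTF3	0.84	1.41	0.60	1.04E-03	1.61E-03	down
RPS6KA1	89.25	148.07	0.60	1.24E-30	2.00E-29	down
JUND	127.78	210.71	0.61	1.88E-36	5.04E-35	down
PLA2G4F	22.98	37.48	0.61	2.67E-10	7.76E-10	down
CACNA2D2	10.30	16.63	0.62	1.02E-08	2.63E-08	down
RPS6KA5	18.57	29.87	0.62	1.84E-15	7.76E-15	down
FLNC	46.98	75.44	0.62	3.90E-09	1.02E-08	down
ARRB1	52.99	84.74	0.63	4.44E-24	3.61E-23	down
NR4A1	201.17	319.66	0.63	5.51E-11	1.72E-10	down
FASLG	1.07	1.70	0.63	4.96E-03	7.29E-03	down
IL1R1	57.71	89.40	0.65	9.55E-17	4.34E-16	down
HSPA2	7.29	11.21	0.65	5.51E-06	1.08E-05	down
PTPN7	16.22	24.78	0.65	3.08E-08	7.57E-08	down
MAP3K14	33.86	51.73	0.65	1.46E-24	1.35E-23	down
MAP2K6	25.29	38.55	0.66	1.60E-10	4.77E-10	down
MKNK1	63.58	95.95	0.66	2.04E-27	2.46E-26	down
HSPB1	60.24	40.01	1.51	3.87E-12	1.24E-11	up
TGFBR1	106.44	70.13	1.52	6.14E-19	3.21E-18	up
STK3	41.26	26.65	1.55	1.64E-18	7.88E-18	up
HSPA6	5.49	3.43	1.60	3.67E-05	6.40E-05	up
ELK1	49.96	30.79	1.62	4.90E-24	3.81E-23	up
DUSP10	27.04	16.22	1.67	3.95E-14	1.59E-13	up
FGF1	4.77	2.79	1.71	9.30E-06	1.75E-05	up
TP53	105.07	59.63	1.76	3.25E-24	2.79E-23	up
HSPA1B	102.12	55.34	1.85	4.49E-24	3.61E-23	up
PDGFRB	166.24	87.76	1.89	8.03E-28	1.02E-26	up
TGFB2	9.23	4.52	2.04	8.04E-14	3.13E-13	up
FGF18	1.90	0.85	2.22	1.27E-05	2.36E-05	up
HSPA8	631.28	273.40	2.31	5.34E-56	1.29E-53	up
CACNG8	7.57	3.27	2.32	7.89E-10	2.19E-09	up
STMN1	77.81	31.07	2.50	1.15E-40	4.63E-39	up
DUSP4	56.69	21.44	2.64	2.53E-22	1.65E-21	up
CDC25B	169.88	60.96	2.79	9.71E-54	7.80E-52	up
IL1A	7.56	2.39	3.17	2.02E-19	1.08E-18	up
NTF4	0.55	0.17	3.23	3.80E-06	7.57E-06	up
CACNG4	3.41	1.03	3.30	8.11E-10	2.22E-09	up
MYC	181.11	49.00	3.70	5.76E-55	6.94E-53	up
FGF20	0.72	0.14	5.29	2.29E-05	4.15E-05	up
FGF19	1.39	0.15	9.42	6.08E-13	2.12E-12	up
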