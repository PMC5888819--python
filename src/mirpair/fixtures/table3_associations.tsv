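gene	gene_tumor_mean	gene_normal_mean	gene_fold_change	mirna	mirna_tumor_mean	mirna_normal_mean	mirna_fold_change	beta	p_raw	p_fdr	seed_match
RASGRP2	6.72	24.73	0.27	hsa-miR-150-5p	14.90	39.17	0.38	.31	<.0001	.0407	0
RASGRP2	6.72	24.73	0.27	hsa-miR-650	4.51	16.60	0.27	.29	.0002	.0407	0
MEF2C	27.15	66.82	0.41	hsa-miR-150-5p	14.90	39.17	0.38	.35	<.0001	.0116	0
MEF2C	27.15	66.82	0.41	hsa-miR-193b-3p	9.12	5.42	1.68	.28	<.0001	.0116	1
MEF2C	27.15	66.82	0.41	hsa-miR-195-5p	3.59	12.18	0.29	.25	.0004	.025	0
MEF2C	27.15	66.82	0.41	hsa-miR-203a	12.52	3.70	3.38	-.30	<.0001	.0116	1
MEF2C	27.15	66.82	0.41	hsa-miR-221-3p	13.53	4.12	3.28	-.26	.0002	.0148	0
MEF2C	27.15	66.82	0.41	hsa-miR-650	4.51	16.60	0.27	.34	<.0001	.0116	0
MAP4K1	7.24	21.46	0.34	hsa-miR-150-5p	14.90	39.17	0.38	.30	<.0001	.0203	0
MAP4K1	7.24	21.46	0.34	hsa-miR-650	4.51	16.60	0.27	.30	.0003	.0488	0
TGFBR1	106.44	70.13	1.52	hsa-let-7i-5p	62.16	39.97	1.56	.25	.0006	.031	1
TGFBR1	106.44	70.13	1.52	hsa-miR-1203	1.76	2.83	0.62	-.23	.0007	.031	0
TGFBR1	106.44	70.13	1.52	hsa-miR-199a-3p	44.83	22.53	1.99	.24	.0007	.031	1
TGFBR1	106.44	70.13	1.52	hsa-miR-199a-5p	20.18	9.28	2.17	.22	.0016	.0458	1
TGFBR1	106.44	70.13	1.52	hsa-miR-2117	1.50	4.09	0.37	-.22	.0011	.0358	1
TGFBR1	106.44	70.13	1.52	hsa-miR-214-3p	13.24	6.13	2.16	.26	.0005	.031	1
TGFBR1	106.44	70.13	1.52	hsa-miR-21-5p	463.11	167.37	2.77	.25	.0006	.031	1
TGFBR1	106.44	70.13	1.52	hsa-miR-23a-3p	174.68	87.53	2.00	.25	.0008	.031	0
TGFBR1	106.44	70.13	1.52	hsa-miR-24-3p	106.75	62.39	1.71	.24	.0009	.0318	1
TGFBR1	106.44	70.13	1.52	hsa-miR-331-3p	14.64	9.30	1.57	.24	.0006	.031	1
TGFBR1	106.44	70.13	1.52	hsa-miR-6071	0.97	1.70	0.57	-.22	.0017	.0458	1
HSPA8	631.28	273.40	2.31	hsa-miR-17-5p	61.04	16.38	3.73	.27	.0003	.0407	1
HSPA8	631.28	273.40	2.31	hsa-miR-203a	12.52	3.70	3.38	.35	<.0001	.0271	0
HSPA8	631.28	273.40	2.31	hsa-miR-221-3p	13.53	4.12	3.28	.28	<.0001	.0271	1
HSPA8	631.28	273.40	2.31	hsa-miR-29b-3p	24.31	9.83	2.47	.27	.0003	.0407	0
HSPA8	631.28	273.40	2.31	hsa-miR-93-5p	41.72	15.20	2.74	.25	.0003	.0407	1
PDGFRB	166.24	87.76	1.89	hsa-miR-193b-3p	9.12	5.42	1.68	.27	.0002	.0181	1
PDGFRB	166.24	87.76	1.89	hsa-miR-199a-3p	44.83	22.53	1.99	.33	<.0001	.0102	0
PDGFRB	166.24	87.76	1.89	hsa-miR-199a-5p	20.18	9.28	2.17	.35	<.0001	.0102	0
PDGFRB	166.24	87.76	1.89	hsa-miR-199b-5p	4.69	1.53	3.07	.34	<.0001	.0102	0
PDGFRB	166.24	87.76	1.89	hsa-miR-214-3p	13.24	6.13	2.16	.38	<.0001	.0102	1
PDGFRB	166.24	87.76	1.89	hsa-miR-934	4.36	0.94	4.66	.46	<.0001	.0102	0
IL1R1	57.71	89.40	0.65	hsa-miR-193b-3p	9.12	5.42	1.68	.31	<.0001	.0203	0
IL1R1	57.71	89.40	0.65	hsa-miR-214-3p	13.24	6.13	2.16	.27	.0003	.0407	1
DUSP4	56.69	21.44	2.64	hsa-miR-193b-3p	9.12	5.42	1.68	-.27	<.0001	.0163	1
DUSP4	56.69	21.44	2.64	hsa-miR-196b-5p	17.89	5.53	3.24	-.31	<.0001	.0163	0
DUSP4	56.69	21.44	2.64	hsa-miR-424-3p	39.81	25.37	1.57	-.29	.0003	.0271	0
RAC2	22.11	37.39	0.59	hsa-miR-150-5p	14.90	39.17	0.38	.39	<.0001	.0203	0
RAC2	22.11	37.39	0.59	hsa-miR-203a	12.52	3.70	3.38	-.28	<.0001	.0203	0
RAC2	22.11	37.39	0.59	hsa-miR-650	4.51	16.60	0.27	.36	<.0001	.0203	0
PDGFRA	88.47	166.61	0.53	hsa-miR-145-5p	132.97	223.14	0.60	.26	.0002	.0163	1
PDGFRA	88.47	166.61	0.53	hsa-miR-150-5p	14.90	39.17	0.38	.24	.0004	.0233	1
PDGFRA	88.47	166.61	0.53	hsa-miR-17-5p	61.04	16.38	3.73	-.28	<.0001	.0136	1
PDGFRA	88.47	166.61	0.53	hsa-miR-19b-3p	29.80	10.42	2.86	-.29	<.0001	.0136	1
PDGFRA	88.47	166.61	0.53	hsa-miR-203a	12.52	3.70	3.38	-.30	<.0001	.0136	1
PDGFRA	88.47	166.61	0.53	hsa-miR-20a-5p	70.78	17.61	4.02	-.28	.0002	.0163	1
PDGFRA	88.47	166.61	0.53	hsa-miR-20b-5p	17.65	3.30	5.35	-.30	<.0001	.0136	1
PDGFRA	88.47	166.61	0.53	hsa-miR-29b-3p	24.31	9.83	2.47	-.27	.0003	.0222	1
PDGFRA	88.47	166.61	0.53	hsa-miR-501-3p	7.07	2.95	2.39	-.25	.0004	.0233	1
PDGFRA	88.47	166.61	0.53	hsa-miR-650	4.51	16.60	0.27	.32	<.0001	.0136	1
MYC	181.11	49.00	3.70	hsa-miR-1246	629.21	412.81	1.52	.27	.0002	.0163	0
MYC	181.11	49.00	3.70	hsa-miR-17-5p	61.04	16.38	3.73	.35	<.0001	.0136	0
MYC	181.11	49.00	3.70	hsa-miR-19b-3p	29.80	10.42	2.86	.27	.0002	.0163	0
MYC	181.11	49.00	3.70	hsa-miR-20a-5p	70.78	17.61	4.02	.33	<.0001	.0136	0
MYC	181.11	49.00	3.70	hsa-miR-20b-5p	17.65	3.30	5.35	.31	.0002	.0163	0
MYC	181.11	49.00	3.70	hsa-miR-3651	58.66	25.92	2.26	.28	.0003	.0188	0
MYC	181.11	49.00	3.70	hsa-miR-375	20.50	54.53	0.38	-.29	<.0001	.0136	0
MYC	181.11	49.00	3.70	hsa-miR-501-3p	7.07	2.95	2.39	.26	.0003	.0188	0
MYC	181.11	49.00	3.70	hsa-miR-583	6.61	3.22	2.05	.26	.0004	.0233	0
MYC	181.11	49.00	3.70	hsa-miR-663a	374.83	234.91	1.60	.28	.0003	.0188	0
MYC	181.11	49.00	3.70	hsa-miR-663b	65.50	32.21	2.03	.33	<.0001	.0136	0
MYC	181.11	49.00	3.70	hsa-miR-92a-3p	121.60	41.18	2.95	.32	<.0001	.0136	0
RASGRP3	25.53	45.22	0.56	hsa-miR-150-5p	14.90	39.17	0.38	.35	<.0001	.0203	1
RASGRP3	25.53	45.22	0.56	hsa-miR-429	13.33	8.29	1.61	-.25	.0003	.0407	1
RASGRP3	25.53	45.22	0.56	hsa-miR-650	4.51	16.60	0.27	.35	<.0001	.0203	0
PRKCB	14.65	53.12	0.28	hsa-miR-150-5p	14.90	39.17	0.38	.38	<.0001	.0102	1
PRKCB	14.65	53.12	0.28	hsa-miR-203a	12.52	3.70	3.38	-.30	<.0001	.0102	1
PRKCB	14.65	53.12	0.28	hsa-miR-650	4.51	16.60	0.27	.35	<.0001	.0102	0
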