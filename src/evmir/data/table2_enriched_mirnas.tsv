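group	mir_id	star	tpm_a33	tpm_epcam	tpm_smv	tpm_cl	log2_a33_cl	log2_epcam_cl	log2_smv_cl	log2_a33_epcam	log2_exos_smv
A33_only	hsa-miR-3677-3p	0	5.06	0.55	0.13	0.48	3.41	0.20	-1.86	3.20	4.33
A33_only	hsa-miR-362-3p	1	10.79	1.92	1.14	1.96	2.46	-0.03	-0.78	2.49	2.42
A33_only	hsa-miR-19b-3p	0	11230.33	2816.61	3876.76	2093.94	2.42	0.43	0.89	2.00	0.81
A33_only	hsa-miR-425-3p	1	81.61	27.53	25.26	15.97	2.35	0.79	0.66	1.57	1.07
A33_only	hsa-miR-19a-3p	0	2550.64	603.95	887.84	585.50	2.12	0.04	0.60	2.08	0.78
A33_only	hsa-miR-378c	0	569.08	152.13	169.49	140.63	2.02	0.11	0.27	1.90	1.05
A33_only	hsa-miR-192-3p	1	23.04	11.16	4.88	5.99	1.94	0.90	-0.30	1.05	1.78
A33_only	hsa-miR-3613-3p	1	8.78	4.07	1.58	2.33	1.91	0.80	-0.56	1.11	1.99
A33_only	hsa-miR-378d	0	30.11	5.99	8.57	8.65	1.80	-0.53	-0.01	2.33	1.02
A33_only	hsa-miR-652-3p	0	43.94	17.97	8.08	12.63	1.80	0.51	-0.64	1.29	1.91
A33_only	hsa-miR-331-5p	0	10.73	4.18	3.30	3.13	1.78	0.42	0.07	1.36	1.14
A33_only	hsa-miR-3664-3p	0	5.06	2.64	1.98	1.59	1.67	0.73	0.31	0.94	0.93
A33_only	hsa-miR-107	0	2272.59	1135.90	1548.19	813.13	1.48	0.48	0.93	1.00	0.11
A33_only	hsa-miR-23a-3p	0	330.59	186.70	91.42	119.89	1.46	0.64	-0.39	0.82	1.48
A33_only	hsa-miR-130b-3p	0	416.83	163.28	181.05	158.83	1.39	0.04	0.19	1.35	0.65
A33_only	hsa-miR-10a-3p	1	155.85	86.56	50.70	60.69	1.36	0.51	-0.26	0.85	1.24
A33_only	hsa-miR-3200-3p	0	6.09	3.41	3.34	2.39	1.35	0.51	0.48	0.84	0.49
A33_only	hsa-miR-140-3p	0	185.34	97.72	91.86	73.00	1.34	0.42	0.33	0.92	0.60
A33_only	hsa-miR-423-5p	0	6932.05	2301.26	1271.59	2787.18	1.31	-0.28	-1.13	1.59	1.82
A33_only	hsa-miR-106b-3p	1	351.00	261.61	168.17	144.56	1.28	0.86	0.22	0.42	0.85
A33_only	hsa-miR-15b-3p	1	28.16	16.93	14.45	11.78	1.26	0.52	0.30	0.73	0.62
A33_only	hsa-miR-629-5p	0	48.58	20.44	23.59	20.32	1.26	0.01	0.22	1.25	0.52
A33_only	hsa-miR-378a-3p	0	9392.79	4318.98	4269.65	4001.47	1.23	0.11	0.09	1.12	0.66
A33_only	hsa-miR-584-5p	0	881.44	287.16	306.83	387.57	1.19	-0.43	-0.34	1.62	0.89
A33_only	hsa-miR-203b-3p	0	19.38	13.47	14.23	8.54	1.18	0.66	0.74	0.53	0.19
A33_only	hsa-miR-1307-5p	1	42.05	9.45	5.36	18.89	1.15	-1.00	-1.82	2.15	2.22
A33_only	hsa-miR-502-3p	0	68.38	33.14	26.14	30.77	1.15	0.11	-0.24	1.05	0.93
A33_only	hsa-miR-143-3p	0	7.80	6.21	4.70	3.66	1.09	0.76	0.36	0.33	0.56
A33_only	hsa-miR-93-3p	1	6.58	2.25	1.45	3.13	1.07	-0.47	-1.11	1.55	1.56
A33_only	hsa-miR-532-5p	0	1241.95	952.83	905.94	603.48	1.04	0.66	0.59	0.38	0.27
A33_only	hsa-miR-365a-3p	0	18.53	10.11	9.14	9.07	1.03	0.16	0.01	0.87	0.63
A33_only	hsa-miR-365b-3p	0	18.53	10.11	9.14	9.07	1.03	0.16	0.01	0.87	0.63
EpCAM_only	hsa-miR-106a-5p	0	1.16	6.49	1.23	0.80	0.54	3.03	0.63	-2.49	1.68
EpCAM_only	hsa-miR-577	0	1075.19	3040.29	1702.18	1114.77	-0.05	1.45	0.61	-1.50	0.31
sMV_only	hsa-miR-675-5p	0	3.60	0.93	11.07	1.86	0.95	-0.99	2.58	1.94	-2.33
sMV_only	hsa-miR-7704	0	1.46	0.93	5.23	1.11	0.39	-0.25	2.23	0.65	-2.18
sMV_only	hsa-miR-98-5p	0	45.77	294.25	1310.52	358.87	-2.97	-0.29	1.87	-2.68	-2.89
sMV_only	hsa-miR-664a-3p	0	12.86	16.27	20.91	8.28	0.64	0.98	1.34	-0.34	-0.52
all_EVs	hsa-miR-4454	0	7.25	1.87	1.01	0.32	4.51	2.55	1.67	1.96	2.12
all_EVs	hsa-let-7f-1-3p	1	14.87	5.44	5.01	0.95	3.96	2.51	2.39	1.45	0.98
all_EVs	hsa-let-7a-3p	1	39.07	21.65	10.41	5.04	2.95	2.10	1.05	0.85	1.52
all_EVs	hsa-miR-574-5p	1	39.86	16.54	42.75	6.21	2.68	1.41	2.78	1.27	-0.63
all_EVs	hsa-miR-451a	0	2.62	2.86	10.32	1.06	1.30	1.43	3.28	-0.12	-1.93
all_EVs	hsa-miR-7641	0	15.66	67.65	123.23	7.64	1.04	3.15	4.01	-2.11	-1.52
A33_EpCAM	hsa-miR-320d	0	547.99	97.22	15.11	7.80	6.13	3.64	0.95	2.49	4.36
A33_EpCAM	hsa-miR-320c	0	609.12	116.84	21.44	11.56	5.72	3.34	0.89	2.38	4.03
A33_EpCAM	hsa-let-7i-3p	1	5.24	3.52	0.40	0.37	3.82	3.24	0.09	0.58	3.45
A33_EpCAM	hsa-miR-374b-5p	0	352.41	113.22	37.52	25.52	3.79	2.15	0.56	1.64	2.59
A33_EpCAM	hsa-miR-320b	0	2227.92	802.30	246.16	327.52	2.77	1.29	-0.41	1.47	2.59
A33_EpCAM	hsa-miR-4664-3p	0	5.36	2.75	0.62	0.95	2.49	1.52	-0.63	0.96	2.70
A33_EpCAM	hsa-miR-320a	0	3801.67	1659.61	726.65	780.45	2.28	1.09	-0.10	1.20	1.88
A33_EpCAM	hsa-miR-221-3p	0	2624.33	1289.18	821.63	579.13	2.18	1.15	0.50	1.03	1.23
A33_EpCAM	hsa-miR-1266-5p	0	8.78	5.61	2.64	2.49	1.82	1.17	0.08	0.65	1.43
A33_EpCAM	hsa-miR-576-3p	0	5.67	5.77	3.08	1.91	1.57	1.60	0.69	-0.03	0.90
A33_EpCAM	hsa-miR-549a	0	33.58	27.86	16.74	11.35	1.56	1.30	0.56	0.27	0.87
A33_EpCAM	hsa-miR-1246	0	348.57	307.55	168.17	126.42	1.46	1.28	0.41	0.18	0.96
A33_EpCAM	hsa-miR-3605-5p	0	77.10	58.37	38.53	29.07	1.41	1.01	0.41	0.40	0.80
A33_EpCAM	hsa-miR-200c-3p	0	1084.09	1430.10	563.31	477.97	1.18	1.58	0.24	-0.40	1.17
A33_EpCAM	hsa-miR-95-3p	0	18.96	29.24	13.66	8.38	1.18	1.80	0.70	-0.63	0.83
A33_EpCAM	hsa-miR-146a-5p	0	230.81	234.18	178.59	107.95	1.10	1.12	0.73	-0.02	0.38
A33_sMV	hsa-miR-193a-3p	0	22.12	8.02	46.92	6.58	1.75	0.29	2.83	1.46	-1.68
A33_sMV	hsa-miR-203a	0	1717.84	1258.57	1475.97	728.62	1.24	0.79	1.02	0.45	0.00
EpCAM_sMV	hsa-miR-204-5p	0	45.41	93.71	96.13	27.64	0.72	1.76	1.80	-1.05	-0.44
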