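river	ld_hist	hw_hist	ar_hist	ne_hist	ld_contemp	hw_contemp	ar_contemp	ne_contemp	fst_22	fst_14	excl_22_pct	excl_14_pct	temporal_change
Neiden	22	0	201	430 (296-760)	7	1	203	Inf (3179-Inf)	0.0009	0.0011	6	3	No
V. Jakobselv	85	9	190	79 (71-91)	32	0	200	169 (148-196)	0.0064	0.0076	16	7	Yes
Alta	5	2	187	Inf (990-Inf)	13	1	190	4860 (856-Inf)	-0.0002	0.0010	2	1	No
Reisa	11	2	185	272 (180-533)	61	1	179	80 (69-94)	0.0041	0.0020	15	10	No
Målselv	10	2	199	Inf (-1361-Inf)	3	0	207	411332# (322-Inf)	-0.0026	-0.0011	13	7	No
Roksdalsvass.	9	0	205	516 (241-Inf)	66	2	206	384 (291-554)	0.0014	0.0023	20	12	No
Namsen	10	0	208	3526 (835-Inf)	14	1	209	914 (549-2550)	0.0013	-0.0012	9	3	No
GaulaST	4	0	206	Inf (2162-Inf)	10	1	208	24753 (1358-Inf)	0.0012	0.0018	12	14	No
Surna	9	0	203	1530# (252-Inf)	11	1	216	Inf (965-Inf)	0.0025	0.0035	34	17	No
Eira	11	2	209	378 (196-3201)	11	0	211	498 (293-1519)	0.0005	0.0000	14	10	No
Bondalselva	9	0	209	1283 (418-Inf)	12	3	NC	34# (26-47)	0.0043	0.0017	6	0	No
Ørstaelva	6	1	214	3678 (450-Inf)	17	0	210	400 (202-6501)	0.0003	-0.0013	0	0	No
GaulaSF	7	3	211	1193 (371-Inf)	19	2	205	439 (311-727)	0.0001	0.0008	17	1	No
Lærdalselva	8	1	193	Inf (-506-Inf)	13	2	200	333 (216-698)	0.0015	0.0010	15	6	No
Vosso	14	1	175	Inf (-304-Inf)	8	4	202	189 (138-294)	0.0179	0.0213	76	67	Yes
Loneelva	17	5	176	984 (348-Inf)	8	2	200	241 (172-390)	0.0120	0.0116	52	29	Yes
Opo	10	1	166	Inf# (-14-Inf)	58	1	184	68 (60-76)	0.0258	0.0279	100	90	Yes
Etne	25	1	209	752 (439-2405)	12	3	209	917 (507-4135)	0.0006	0.0000	5	5	No
Figgjo	9	1	204	Inf (-1638-Inf)	14	2	210	Inf (1070-Inf)	0.0048	0.0058	38	4	Yes
Numedalslågen	9	1	194	Inf (1194-Inf)	14	1	210	653 (383-2050)	0.0032	0.0051	29	18	No
Berbyelva	19	0	156	81 (67-101)	19	4	166	245 (194-327)	0.0053	0.0071	16	7	Yes
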