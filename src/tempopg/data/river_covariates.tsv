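river	years_counted	unweighted_escapee_pct	weighted_escapee_pct
Neiden	1	12	2
V. Jakobselv	18	30	20
Alta	15	6	5
Reisa	12	31	5
Målselv	15	16	8
Roksdalsvass.	19	7	3
Namsen	21	27	11
GaulaST	16	6	4
Surna	7	28	14
Eira	7	16	17
Bondalselva	10	27	17
Ørstaelva	15	41	22
GaulaSF	13	31	17
Lærdalselva	4	2	4
Vosso	14	45	29
Loneelva	16	8	7
Opo	2	50	89
Etne	19	57	35
Figgjo	14	9	9
Numedalslågen	15	7	5
Berbyelva	6	4	2
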