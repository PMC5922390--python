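gene	panel_class	all_unique	all_germline	all_somatic	lung_unique	lung_germline	lung_somatic
ALK	tumor_driver	32	1317	14	6	93	1
BRAF	tumor_driver	23	5	29	3	0	3
CDKN2A	tumor_driver	22	35	14	5	2	3
CEBPA	tumor_driver	8	2	6	0	0	0
DNMT3A	tumor_driver	22	12	11	1	1	0
EGFR	tumor_driver	29	315	16	6	15	6
ERBB2	tumor_driver	38	921	15	7	68	0
EZH2	tumor_driver	12	117	8	1	3	0
FLT3	tumor_driver	25	846	5	6	64	1
IDH1	tumor_driver	9	85	5	2	2	0
IDH2	tumor_driver	10	9	5	0	0	0
JAK2	tumor_driver	18	37	5	0	0	0
KIT	tumor_driver	19	138	10	5	8	5
KMT2A	tumor_driver	57	72	18	3	2	1
KRAS	tumor_driver	16	3	77	4	0	7
MET	tumor_driver	28	58	11	5	7	1
NOTCH1	tumor_driver	59	143	17	8	6	2
NPM1	tumor_driver	2	1	1	0	0	0
NRAS	tumor_driver	10	1	18	0	0	0
PDGFRA	tumor_driver	24	169	14	2	9	0
PDGFRB	tumor_driver	28	98	8	8	11	1
PGR	tumor_driver	31	377	15	7	21	2
PIK3CA	tumor_driver	31	96	82	2	6	1
PTEN	tumor_driver	33	780	24	2	56	0
RET	tumor_driver	22	244	9	7	21	0
APC	inherited_risk	85	692	58	7	48	1
BMPR1A	inherited_risk	5	334	2	1	17	0
EPCAM	inherited_risk	13	464	0	3	37	0
MLH1	inherited_risk	15	295	4	4	26	1
MSH2	inherited_risk	23	40	5	4	5	0
MSH6	inherited_risk	25	273	7	2	18	0
PMS2	inherited_risk	44	1558	10	13	110	3
POLD1	inherited_risk	30	208	7	4	11	0
POLE	inherited_risk	58	398	18	16	34	3
STK11	inherited_risk	13	6	7	3	0	3
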