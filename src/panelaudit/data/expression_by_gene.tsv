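gene	all_assessed	all_not_expressed	all_patients	lung_assessed	lung_not_expressed	lung_patients
ALK	13	10	9	0	0	0
BRAF	24	0	0	2	0	0
CDKN2A	13	2	2	3	0	0
CEBPA	5	1	1	0	0	0
DNMT3A	11	1	1	0	0	0
EGFR	16	1	1	6	0	0
ERBB2	14	1	1	0	0	0
EZH2	8	0	0	0	0	0
FLT3	5	4	4	1	1	1
IDH1	5	0	0	0	0	0
IDH2	5	0	0	0	0	0
JAK2	5	1	1	0	0	0
KIT	8	5	5	4	2	2
KMT2A	18	2	2	1	0	0
KRAS	70	2	2	6	1	1
MET	11	3	3	1	1	1
NOTCH1	16	1	1	2	0	0
NPM1	1	0	0	0	0	0
NRAS	15	0	0	0	0	0
PDGFRA	14	11	8	0	0	0
PDGFRB	8	3	3	1	1	1
PGR	14	13	11	1	1	1
PIK3CA	75	0	0	1	0	0
PTEN	23	1	1	0	0	0
RET	9	7	6	0	0	0
APC	54	4	4	1	0	0
BMPR1A	1	0	0	0	0	0
EPCAM	0	0	0	0	0	0
MLH1	4	0	0	1	0	0
MSH2	5	0	0	0	0	0
MSH6	7	1	1	0	0	0
PMS2	10	0	0	3	0	0
POLD1	7	0	0	0	0	0
POLE	16	1	1	2	0	0
STK11	7	0	0	3	0	0
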