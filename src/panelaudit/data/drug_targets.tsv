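gene	drugs
ALK	Crizotinib;Alectinib;Ceritinib;Brigatinib
BRAF	Vemurafenib;Dabrafenib;Cobimetinib;Trametinib
DNMT3A	Azacitidine;Decitabine
EGFR	Erlotinib;Afatinib;Gefitinib
ERBB2	Neratinib;Lapatinib
JAK2	Ruxolitinib
KIT	Imatinib;Dasatinib;Regorafenib
MET	Crizotinib;Cabozantinib
PDGFRA	Axitinib;Regorafenib
PDGFRB	Axitinib;Regorafenib
PIK3CA	Idelalisib;Everolimus
RET	Cabozantinib;Vandetanib
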