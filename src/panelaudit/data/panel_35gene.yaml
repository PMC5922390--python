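# 35-gene lung-cancer panel: 25 somatic tumor-driver genes and 10 inherited
# cancer-risk genes.  Coordinates are GRCh37 gene spans (1-based, closed);
# cds_length is the protein-coding sequence length in bases of the canonical
# transcript and is used for the gene-size correlation and for
# length-proportional simulation of variant placement.
genes:
  - {gene: ALK,    class: tumor_driver,   cds_length: 4863,  intervals: [[chr2, 29415640, 30144432]]}
  - {gene: BRAF,   class: tumor_driver,   cds_length: 2301,  intervals: [[chr7, 140419127, 140624564]]}
  - {gene: CDKN2A, class: tumor_driver,   cds_length: 471,   intervals: [[chr9, 21967751, 21995300]]}
  - {gene: CEBPA,  class: tumor_driver,   cds_length: 1077,  intervals: [[chr19, 33790840, 33793470]]}
  - {gene: DNMT3A, class: tumor_driver,   cds_length: 2739,  intervals: [[chr2, 25455845, 25565459]]}
  - {gene: EGFR,   class: tumor_driver,   cds_length: 3633,  intervals: [[chr7, 55086714, 55324313]]}
  - {gene: ERBB2,  class: tumor_driver,   cds_length: 3768,  intervals: [[chr17, 37844167, 37886679]]}
  - {gene: EZH2,   class: tumor_driver,   cds_length: 2238,  intervals: [[chr7, 148504475, 148581413]]}
  - {gene: FLT3,   class: tumor_driver,   cds_length: 2982,  intervals: [[chr13, 28577411, 28674729]]}
  - {gene: IDH1,   class: tumor_driver,   cds_length: 1245,  intervals: [[chr2, 209100953, 209119806]]}
  - {gene: IDH2,   class: tumor_driver,   cds_length: 1359,  intervals: [[chr15, 90626277, 90645736]]}
  - {gene: JAK2,   class: tumor_driver,   cds_length: 3399,  intervals: [[chr9, 4985033, 5128183]]}
  - {gene: KIT,    class: tumor_driver,   cds_length: 2931,  intervals: [[chr4, 55524095, 55606881]]}
  - {gene: KMT2A,  class: tumor_driver,   cds_length: 11910, intervals: [[chr11, 118307205, 118397539]]}
  - {gene: KRAS,   class: tumor_driver,   cds_length: 567,   intervals: [[chr12, 25358180, 25403854]]}
  - {gene: MET,    class: tumor_driver,   cds_length: 4227,  intervals: [[chr7, 116312444, 116438440]]}
  - {gene: NOTCH1, class: tumor_driver,   cds_length: 7668,  intervals: [[chr9, 139388896, 139440238]]}
  - {gene: NPM1,   class: tumor_driver,   cds_length: 885,   intervals: [[chr5, 170814120, 170838141]]}
  - {gene: NRAS,   class: tumor_driver,   cds_length: 570,   intervals: [[chr1, 115247085, 115259515]]}
  - {gene: PDGFRA, class: tumor_driver,   cds_length: 3270,  intervals: [[chr4, 55095264, 55164414]]}
  - {gene: PDGFRB, class: tumor_driver,   cds_length: 3321,  intervals: [[chr5, 149493400, 149535435]]}
  - {gene: PGR,    class: tumor_driver,   cds_length: 2802,  intervals: [[chr11, 100900355, 101001255]]}
  - {gene: PIK3CA, class: tumor_driver,   cds_length: 3207,  intervals: [[chr3, 178866311, 178952497]]}
  - {gene: PTEN,   class: tumor_driver,   cds_length: 1212,  intervals: [[chr10, 89623195, 89728532]]}
  - {gene: RET,    class: tumor_driver,   cds_length: 3345,  intervals: [[chr10, 43572475, 43625799]]}
  - {gene: APC,    class: inherited_risk, cds_length: 8532,  intervals: [[chr5, 112043195, 112181936]]}
  - {gene: BMPR1A, class: inherited_risk, cds_length: 1599,  intervals: [[chr10, 88516396, 88684945]]}
  - {gene: EPCAM,  class: inherited_risk, cds_length: 945,   intervals: [[chr2, 47596287, 47614167]]}
  - {gene: MLH1,   class: inherited_risk, cds_length: 2271,  intervals: [[chr3, 37034841, 37092337]]}
  - {gene: MSH2,   class: inherited_risk, cds_length: 2805,  intervals: [[chr2, 47630206, 47710367]]}
  - {gene: MSH6,   class: inherited_risk, cds_length: 4083,  intervals: [[chr2, 48010221, 48034092]]}
  - {gene: PMS2,   class: inherited_risk, cds_length: 2589,  intervals: [[chr7, 6012870, 6048737]]}
  - {gene: POLD1,  class: inherited_risk, cds_length: 3324,  intervals: [[chr19, 50887580, 50921273]]}
  - {gene: POLE,   class: inherited_risk, cds_length: 6861,  intervals: [[chr12, 133200348, 133263951]]}
  - {gene: STK11,  class: inherited_risk, cds_length: 1302,  intervals: [[chr19, 1205798, 1228430]]}
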