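taxon,tooth,age_years
cervus,m1,0.5
cervus,m2,1.25
cervus,m3,2.5
cervus,M1,0.5
cervus,M2,1.25
cervus,M3,2.5
equus,m1,1.0
equus,m2,2.0
equus,m3,3.5
equus,M1,1.0
equus,M2,2.0
equus,M3,3.5
bos_bison,m1,0.75
bos_bison,m2,1.5
bos_bison,m3,2.75
bos_bison,M1,0.75
bos_bison,M2,1.5
bos_bison,M3,2.75
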