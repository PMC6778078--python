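taxon,level,meso_n,mws,mws_sd,micro_n,lsr,ns,ns_cv_star,ns_sd,np,np_cv_star,np_sd,pct_lp,pct_g,pct_xs,pct_ch,sws,layout_uncertain
cervus,4,12,2.3,0.49,29,72.41,16.93,0.10,1.66,26.17,0.18,4.69,89.66,0,48.28,3.45,0.93,
cervus,6,2,3,1.41,15,73.33,15.80,0.10,1.60,21.83,0.16,3.34,93.33,0,46.67,0,0.73,
cervus,7,24,2.3,1.09,34,47.05,17.35,0.12,1.97,25.71,0.15,3.84,100,14.71,47.06,8.82,0.68,yes
cervus,8,20,2.7,0.93,31,54.83,17.18,0.12,2.06,21.82,0.19,4.03,100,0,25.81,12.90,0.94,
cervus,9,1,1,,8,62.50,17.06,0.14,2.28,23.69,0.10,2.31,100,0,50,25,0.63,
equus,4,,,,,,,,,,,,,,,,,
equus,6,,,,1,,,,,,,,,,,,,
equus,7,7,5.3,0.76,10,0,21.80,0.18,3.77,27.45,,4.62,100,0,90,20,1,
equus,8,14,4.4,0.84,30,6.67,21.28,0.11,2.27,24.17,0.13,3.14,93.33,0,70,13.33,1.13,
equus,9,1,5,,2,0,25.25,0.11,2.48,13.50,0.18,2.12,100,0,100,100,1,
bos_bison,4,,,,1,,,,,,,,,,,,,
bos_bison,6,,,,4,0,21.25,0.08,1.66,13.88,,0.85,,0,75,100,1,yes
bos_bison,7,2,3,0,21,28.57,20.38,0.15,3.04,27.24,0.19,5.12,95.24,0,61.90,19.05,1.05,
bos_bison,8,1,4,,13,0,21.69,0.12,2.44,24.73,0.11,2.77,100,0,76.92,7.69,0.77,
bos_bison,9,,,,,,,,,,,,,,,,,
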