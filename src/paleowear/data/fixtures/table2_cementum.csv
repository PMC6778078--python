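taxon,level,specimen_id,tooth_code,n_cb,lcb,pct_dev,season
cervus,4,CL 1,m2 R,OB + 3 (+TB),TB,35.75,Middle Good Season
cervus,4,CL 249,m2 L,13,OB,,Bad Season
cervus,4,CL 262,M1 R,5 (+TB),TB,23.89,Beginning Good Season
cervus,4,CL 268,m1 R,7,OB,,Bad Season
cervus,4,CL 275,m3 R,3 (+TB),TB,38.86,Middle Good Season
cervus,7,CL 97,m3 R,5 (+TB),TB,10.39,Beginning Good Season
cervus,7,CL 158,M2 R,9,OB,,Bad Season
cervus,7,CL 197,M2 R,,,,No data
cervus,7,CL 222,m3 L,4 (+TB),TB,52.24,Middle Good Season
cervus,7,CL 225,m2 L,6 (+TB),TB,19.67,Beginning Good Season
cervus,8,CL 2,m3 R,5,OB,,Bad Season
cervus,8,CL 3,m2 R,8 (+TB),TB,14.19,Beginning Good Season
cervus,8,CL 302,m2 R,4,OB,,Bad Season
cervus,8,CL 349,M1 R,9 (+TB) (at least),TB,28.82,Beginning Good Season
cervus,8,CL 360,m1 L,5 (+TB),TB,82.51,End Good Season
bos_bison,6,CL 112,m2 L,,,,No data
bos_bison,7,CL 146,m2 L,,,,No data
bos_bison,7,CL 327,m3 R,,,,No data
bos_bison,8,CL 50,M1 R,5 (+TB),TB,48.78,Middle Good Season
bos_bison,8,CL 51,M1 L,5 (+TB),TB,29.85,Beginning Good Season
bos_bison,8,CL 291,m1 L,3 (+TB),TB,92.84,End Good Season
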