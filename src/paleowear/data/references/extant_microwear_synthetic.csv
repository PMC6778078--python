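code,taxon,diet,ns,np
AA,Alces alces,browser,10.4,28.6
AM,Antilocapra americana,browser,15.8,21.9
BE,Boocercus eurycerus,browser,12.1,23.4
DB,Diceros bicornis,browser,8.9,25.2
GC,Giraffa camelopardalis,browser,12.6,31.8
LW,Litocranius walleri,browser,11.2,19.6
Ly,Loxodonta cyclotis,browser,16.4,25.3
Mr,Muntiacus reevesi,browser,17.8,28.3
ab,Alcelaphus buselaphus,grazer,23.4,12.1
bu,Bubalus mindorensis,grazer,18.2,15.7
ct,Connochaetes taurinus,grazer,24.6,10.8
eg,Equus grevyi,grazer,20.9,14.2
ha,Hippopotamus amphibius,grazer,17.6,17.9
hn,Hippotragus niger,grazer,25.2,11.5
ke,Kobus ellipsiprymnus,grazer,22.9,12.6
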