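clade,richness,missing
angor,7,0
annulimana,16,14
calloptera,8,5
canalinea,14,12
cardini,16,9
clefta,3,0
dreyfusi,9,8
funebris,7,6
guarani,16,11
immigrans,104,84
macroptera,5,4
melanica,13,4
mesophragamatica,13,7
nannoptera,5,2
pallidipennis,1,0
polychaeta,10,3
quadrisetata,12,2
quinaria,33,25
repleta,101,57
robusta,16,2
sticta,1,0
testacea,4,3
tripunctata,79,57
virilis,13,1
Hawaiian,1000,972
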