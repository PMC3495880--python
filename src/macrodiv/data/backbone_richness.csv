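clade,richness
angor,7
polychaeta,10
annulimana,16
nannoptera,5
dreyfusi,9
canalinea,14
mesophragamatica,13
repleta,101
virilis,13
robusta_clade,44
Hawaiian,1000
immigrans,104
tripunctata_clade,170
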