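character,code,meaning
geography,0,cosmopolitan (found in more than one region)
geography,1,European
geography,2,African
geography,3,North American
geography,4,Neotropical
geography,5,Asian
geography,6,Australia + Oceania
ecology,0,generalist (more than one substrate; no cacti)
ecology,1,mycophagous
ecology,2,frugivorous
ecology,3,sap feeder
ecology,4,cactophilic
ecology,5,generalist + cactophilic
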