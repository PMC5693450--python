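species,ecv_cm3,group_size,neocortex_ratio,life_expectancy
ring_tailed_lemur,23,16,1.2,18
lion_tailed_macaque,85,18,2.2,25
rhesus_macaque,92,42,2.4,28
sooty_mangabey,104,68,2.6,27
orangutan,380,3,3.1,45
gorilla,480,11,2.9,40
chimpanzee,390,52,3.2,45
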