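class,sequence,rank,tm_K,tm_se_K,deltaF_kcal_mol,deltaF_se_kcal_mol
screen,EKGEKG,1,432,8,-1.7,0.5
screen,EKGDKG,2,421,5,3.0,0.4
screen,EKGEXG,3,411,4,2.1,0.4
screen,EKGKEG,4,410,5,4.5,0.2
screen,EXGEKG,5,410,7,1.6,0.3
screen,DMGCIG,97,371,5,-3.5,0.2
screen,EDGDDG,218,330,1,-17.1,0.3
engineered,EKGEKG,1,424,7,4.5,0.3
engineered,EKGDKG,2,420,6,3.3,0.2
engineered,EKGEXG,3,418,4,4.8,0.4
engineered,EKGKEG,4,429,2,5.6,0.2
engineered,EXGEKG,5,428,4,5.7,0.2
collagen,PPGPPG,,555,8,3.8,0.2
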