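variable,best_model,probability,bf12,evidence
sum_dig_FA,m2,0.919,11,Strong
OSIPI,m3,0.978,45,Strong
PI_lipid,m4,0.77,7,Strong
OSIDI,m1,0.921,12,Strong
OSIMes,m1,0.999,898,Decisive
Mes_lipid,m4,0.459,2,Negligible
OSILI,m1,0.999,2161,Decisive
LI_lipid,m4,0.436,2,Negligible
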