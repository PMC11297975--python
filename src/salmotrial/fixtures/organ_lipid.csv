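pen_id,size,rapeseed_oil,sum_dig_FA,OSIPI,PI_lipid,OSIDI,OSIMes,Mes_lipid,OSILI,LI_lipid
S0-0,0,0,189,2.6,66,0.5,6.2,610,1.21,34
S0-5,0,5,197,2.9,90,0.4,6.6,589,1.27,30
S0-9,0,9,207,2.6,77,0.5,6.3,830,1.26,35
S0-14,0,14,214,2.8,107,0.5,6.5,688,1.33,35
S0-19,0,19,238,2.7,121,0.5,6.5,726,1.39,46
S0-24,0,24,251,2.9,129,0.5,6.6,648,1.29,55
S1-0,1,0,181,2.0,69,0.6,6.4,633,1.23,27
S1-5,1,5,187,1.9,62,0.5,6.3,694,1.27,29
S1-9,1,9,211,2.3,84,0.4,7.0,736,1.23,30
S1-14,1,14,217,2.2,66,0.5,6.8,697,1.29,32
S1-19,1,19,242,2.4,87,0.5,7.3,796,1.26,32
S1-24,1,24,250,2.3,97,0.5,6.7,728,1.32,36
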