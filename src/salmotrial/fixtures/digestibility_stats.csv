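nutrient,best_model,probability,bf12,evidence
CP,m3,0.863,6,Substantial
Sum FA,m2,0.961,25,Strong
14:0,m2,0.944,18,Strong
16:0,m2,0.922,12,Strong
18:0,m2,0.886,10,Strong
20:0,m2,0.844,10,Strong
16:1n7,m1,0.901,12,Strong
18:1n9,m1,0.473,1,Negligible
20:1,m2,0.530,1,Negligible
22:1n9,m2,0.929,14,Strong
18:2n6,m2,0.893,12,Strong
20:4n6,m1,0.902,9,Substantial
18:3n3,m2,0.893,14,Strong
20:5n3,m1,0.944,19,Strong
22:5n3,m1,0.804,4,Substantial
22:6n3,m1,0.928,13,Strong
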