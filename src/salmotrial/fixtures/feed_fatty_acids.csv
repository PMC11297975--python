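fatty_acid,oil_0,oil_5,oil_9,oil_14,oil_19,oil_24
12:0,0.02,0.02,0.02,0.02,0.01,0.01
14:0,1.88,1.58,1.32,1.02,0.87,0.60
16:0,5.24,4.62,4.08,3.47,3.24,2.72
18:0,1.28,1.18,1.08,0.99,0.97,0.89
20:0,0.25,0.25,0.23,0.21,0.21,0.21
22:0,0.18,0.20,0.18,0.20,0.21,0.22
24:0,0.04,0.04,0.04,0.04,0.05,0.05
16:1,1.91,1.59,1.32,1.06,0.88,0.62
18:1,3.03,4.99,6.68,8.21,10.15,11.87
20:1,0.42,0.42,0.42,0.41,0.43,0.45
22:1n9,0.07,0.08,0.09,0.10,0.12,0.16
22:1n11,0.27,0.24,0.22,0.20,0.19,0.18
24:1,0.12,0.10,0.08,0.08,0.07,0.06
18:2n6,1.04,1.90,2.56,3.30,4.02,4.65
18:3n3,0.22,0.53,0.78,1.03,1.32,1.60
18:3n6,0.06,0.06,0.05,0.04,0.03,0.03
20:3n3,0.02,0.01,0.01,0.01,0.01,0.01
20:3n6,0.05,0.05,0.03,0.03,0.02,0.01
20:4n6,0.29,0.24,0.20,0.16,0.13,0.09
20:5n3,3.79,3.16,2.55,2.03,1.70,1.17
22:5n3,0.44,0.37,0.28,0.24,0.19,0.13
22:6n3,1.63,1.38,1.11,0.92,0.80,0.59
Other,4.03,3.49,2.98,2.55,2.11,1.80
Total,26.3,26.5,26.3,26.3,27.7,28.1
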