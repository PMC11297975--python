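nutrient,oil_0,oil_5,oil_9,oil_14,oil_19,oil_24
CP,86.8,86.2,88.1,86.1,87.8,86.6
Sum FA,81.0,81.0,87.5,89.0,92.0,94.0
14:0,75.0,73.0,81.0,82.0,87.5,91.0
16:0,60.5,58.5,68.5,70.5,79.0,85.0
18:0,41.5,37.5,47.0,48.0,57.0,63.5
20:0,52.5,50.5,56.0,56.5,64.0,70.0
16:1n7,96.5,95.0,98.0,98.0,98.5,98.5
18:1n9,93.0,93.5,97.0,97.0,98.0,98.5
20:1,89.5,88.0,94.0,93.5,95.5,95.5
22:1n9,80.0,81.5,89.0,91.0,94.0,95.5
18:2n6,89.0,92.5,96.0,96.0,97.0,97.0
20:4n6,97.0,96.5,98.5,98.0,98.0,97.5
18:3n3,90.0,94.5,97.0,97.5,98.0,98.5
20:5n3,98.0,97.5,99.0,99.0,99.0,99.0
22:5n3,97.0,95.0,97.5,97.5,97.5,96.5
22:6n3,96.0,95.0,97.0,97.0,97.0,96.5
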