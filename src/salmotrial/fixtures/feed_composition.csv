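item,section,unit,oil_0,oil_5,oil_9,oil_14,oil_19,oil_24
Fish meal NA LT,ingredient,% of diet,13.0,13.0,13.0,13.0,13.0,13.0
Krill 56,ingredient,% of diet,2.0,2.0,2.0,2.0,2.0,2.0
Soya SPC,ingredient,% of diet,23.8,23.8,23.8,23.8,23.8,23.8
Pea protein 65,ingredient,% of diet,7.5,7.5,7.5,7.5,7.5,7.5
Guar meal,ingredient,% of diet,8.0,8.0,8.0,8.0,8.0,8.0
Wheat milling quality,ingredient,% of diet,13.5,13.5,13.5,13.5,13.5,13.5
Fish oil,ingredient,% of diet,31.2,26.5,21.8,17.1,12.4,7.7
Rapeseed oil,ingredient,% of diet,0.0,4.7,9.4,14.1,18.8,23.5
Choline chloride 70% dry,ingredient,% of diet,0.03,0.03,0.03,0.03,0.03,0.03
Vitamin and mineral mix,ingredient,% of diet,2.1,2.1,2.1,2.1,2.1,2.1
Lucantin Pink CWD 10%,ingredient,% of diet,0.1,0.1,0.1,0.1,0.1,0.1
Yttrium oxide,ingredient,% of diet,0.1,0.1,0.1,0.1,0.1,0.1
Crude protein,analyzed,% of diet,38.6,38.3,38.6,38.3,39.7,39.6
Sum fatty acids,analyzed,% of diet,26.3,26.5,26.3,26.3,27.7,28.1
Choline,analyzed,mg/kg,1490,1520,1680,1430,1500,1520
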