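# region -> demographic zone assignment (north to south: N, C1, C2, S1, S2)
region	zone
Arica y Parinacota	N
Tarapacá	N
Antofagasta	N
Atacama	N
Coquimbo	N
Valparaíso	C1
Metropolitana	C1
O'Higgins	C1
Maule	C2
Bio-bio	C2
Araucanía	S1
Los Ríos	S1
Los Lagos	S1
Aysén	S2
Magallanes	S2
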