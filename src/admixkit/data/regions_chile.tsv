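# regions: sampling counts and percentage fractions (census_fraction empty when unknown)
region	n_sample	sample_fraction	census_fraction
Arica y Parinacota	2	0.6	1.1
Tarapacá	5	1.6	1.8
Antofagasta	2	0.6	3.4
Atacama	3	1.0	1.6
Coquimbo	4	1.3	4.2
Valparaíso	29	9.3	10.3
Metropolitana	124	39.6	40.3
O'Higgins	6	1.9	5.2
Maule	9	2.9	5.9
Bio-bio	32	10.2	11.9
Araucanía	26	8.3	5.7
Los Ríos	26	8.3	2.2
Los Lagos	21	6.7	4.9
Aysén	9	2.9	0.6
Magallanes	3	1.0	0.9
Unknown	12	3.8
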