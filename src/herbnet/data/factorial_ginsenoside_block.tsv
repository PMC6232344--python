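Ginsenoside Rg1	Ginsenoside Rb1	Notoginsenoside R1	n	mean	sd
2.5	2.5	2.5	6	1.645	0.053
2.5	2.5	5.0	6	1.626	0.036
2.5	5.0	2.5	6	1.643	0.034
2.5	5.0	5.0	6	1.578	0.053
5.0	2.5	2.5	6	1.533	0.070
5.0	2.5	5.0	6	1.487	0.055
5.0	5.0	2.5	6	1.380	0.061
5.0	5.0	5.0	6	1.283	0.045
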