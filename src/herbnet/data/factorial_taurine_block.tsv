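Taurine	Paeonol	Geniposide	n	mean	sd
2.5	2.5	2.5	5	1.526	0.043
2.5	2.5	5.0	5	1.513	0.087
2.5	5.0	2.5	5	1.502	0.059
2.5	5.0	5.0	5	1.518	0.029
5.0	2.5	2.5	5	1.517	0.078
5.0	2.5	5.0	5	1.314	0.087
5.0	5.0	2.5	5	1.285	0.048
5.0	5.0	5.0	5	1.261	0.087
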