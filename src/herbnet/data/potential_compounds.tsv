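id	name	ingredient	ob	dl	evidence
PR1	Paeoniflorin	PR	53.87	0.79	False
PR3	Ethyl linoleate	PR	42	0.19	False
PR4	Albiflorin	PR	30.25	0.77	False
PR8	Paeonol	PR	28.79	0.04	True
PR10	Catechin	PR	54.83	0.24	False
PR14	Kaempferol	PR	41.88	0.24	False
PR15	Naringenin	PR	33.23	0.24	False
PR19	Oleic acid	PR	33.13	0.14	False
PR20	Baicalein	PR	33.52	0.21	False
RO5	Piceatannol	RO	72.29	0.13	False
RO7	Emodin	RO	24.4	0.24	False
RO8	Rhein	RO	47.07	0.28	False
RO10	Aloe-emodin	RO	83.38	0.24	False
RO14	Eupatin	RO	50.8	0.41	False
RG1	Catalpol	RG	5.07	0.44	True
RG6	Geniposide	RG	3.78	0.44	True
RG12	β-Sitosterol	RG	36.91	0.75	False
RG14	Stigmasterol	RG	43.87	0.76	False
PS5	Hederagenin	PS	36.91	0.75	False
PS7	Betulinic acid	PS	55.38	0.78	False
PS9	Quercetin	PS	46.43	0.28	False
PN1	Ginsenosides Rg1	PN	-	-	True
PN2	Ginsenoside Rb1	PN	6.24	0.04	True
PN3	Notoginsenoside R1	PN	5.43	0.13	True
PN17	(-)-alpha-Cedrene	PN	55.56	0.10	False
PN19	Diop	PN	43.59	0.39	False
PN20	Mandenol	PN	42	0.19	False
AT2	β-Asarone	AT	35.61	0.06	True
AT5	Astragalin	AT	14.03	0.74	False
AT7	N-trans-feruloyltyramine	AT	86.71	0.26	False
AT11	Apigenin	AT	23.06	0.21	False
AT14	Marmesin	AT	50.28	0.18	False
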