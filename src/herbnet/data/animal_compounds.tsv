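id	name	ingredient	ob	dl	evidence
BB1	Taurine	BB	-	-	True
PA1	Lumbrokinase	PA	-	-	True
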