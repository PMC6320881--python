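# name	label	attachment_mode	formula_delta
n-acetyl	NAc	replaces-hydroxyl	C:2,H:3,N:1
n-glycolyl	NGc	replaces-hydroxyl	C:2,H:3,N:1,O:1
amino	N	replaces-hydroxyl	H:1,N:1,O:-1
acetyl	Ac	replaces-hydroxyl-H	C:2,H:2,O:1
methyl	Me	replaces-hydroxyl-H	C:1,H:2
sulfate	S	replaces-hydroxyl-H	O:3,S:1
phosphate	P	replaces-hydroxyl-H	H:1,O:3,P:1
pyruvate	Py	replaces-hydroxyl-H	C:3,H:2,O:2
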