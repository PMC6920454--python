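# Second, unrelated two-generation keratoconus family (synthetic reconstruction).
# WES-selected: patients 301 and 303, controls 201 and 202. Parent 201 is an
# unaffected carrier (incomplete penetrance). Haplotype labels are synthetic.
F2	201	0	0	1	1	L	WES
F2	202	0	0	2	1	U	WES
F2	301	201	202	1	2	L	WES
F2	302	201	202	2	1	U	NONE
F2	303	201	202	2	2	L	WES
F2	304	201	202	1	1	U	NONE
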