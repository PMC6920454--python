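# Four-generation autosomal-dominant keratoconus family (synthetic reconstruction).
# Named members, affection, haplotype labels, and sequencing sets follow the
# published description; connecting spouses/founders are invented. Columns:
# FID IID FATHER MOTHER SEX AFF HAP SEQ
F1	I1	0	0	1	2	L	NONE
F1	I2	0	0	2	1	U	NONE
F1	II5	I1	I2	1	2	L	WES
F1	II6	0	0	2	1	U	NONE
F1	III3	0	0	2	1	U	NONE
F1	III4	II5	II6	1	2	L	WES
F1	III5	II5	II6	1	2	L	WES
F1	III6	0	0	2	1	U	NONE
F1	III7	II5	II6	1	2	L	WGS
F1	III8	0	0	2	1	U	NONE
F1	III9	II5	II6	2	2	L	NONE
F1	III12	II5	II6	2	1	U	WES
F1	III13	II5	II6	2	1	U	WES
F1	III14	II5	II6	1	1	U	WES
F1	IV2	III4	III3	1	2	L	WGS
F1	IV4	III4	III3	2	2	L	WES
F1	IV5	III4	III3	1	2	L	BOTH
F1	IV8	III7	III8	2	1	U	WGS
F1	IV9	III5	III6	1	1	L	NONE
F1	IV10	III5	III6	2	2	L	BOTH
F1	IV12	III5	III6	1	2	L	WES
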