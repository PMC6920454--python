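key	rsid	gene	maf	hgvs_c	consequence_class
5:103154707:T:G	rs35671301	PPIP5K2	0.0069	c.1255T>G	missense
5:96408333:G:A	rs373951075	PCSK1	0.00026	c.1096-10G>A	splice_region
5:103183000:A:G	rs781831998	PPIP5K2	0.00006	c.2528A>G	missense
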