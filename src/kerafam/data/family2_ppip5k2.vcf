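##fileformat=VCFv4.2
##source=kerafam-fixture
##contig=<ID=5>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	201	202	301	302	303	304
5	103183000	rs781831998	A	G	.	PASS	.	GT:DP:GQ	0/1:78:99	0/0:81:99	0/1:84:99	0/0:80:99	0/1:79:99	0/0:77:99
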