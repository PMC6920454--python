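##fileformat=VCFv4.2
##source=kerafam-fixture
##contig=<ID=5>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	III7	IV2	IV5	IV8	IV10
5	96408333	rs373951075	G	A	.	PASS	.	GT:DP:GQ	0/1:36:99	0/1:40:99	0/1:42:99	0/0:38:99	0/1:35:99
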