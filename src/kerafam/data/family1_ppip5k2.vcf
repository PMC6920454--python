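##fileformat=VCFv4.2
##source=kerafam-fixture
##contig=<ID=5>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	II5	III4	III5	III7	III9	III12	III13	III14	IV2	IV4	IV5	IV8	IV9	IV10	IV12
5	103154707	rs35671301	T	G	.	PASS	.	GT:DP:GQ	0/1:82:99	0/1:85:99	0/1:79:99	0/1:41:99	0/0:80:99	0/0:88:99	0/0:76:99	0/0:81:99	0/1:38:99	0/1:90:99	0/1:84:99	0/0:35:99	0/0:77:99	0/1:86:99	0/1:83:99
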