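Packaged fixtures
=================

All files here are SYNTHETIC reconstructions built from published summary
descriptions; no sequencing data were deposited, so none of this is real
patient data.

family1.ped / family1_ppip5k2.vcf / family1_pcsk1.vcf
    Four-generation autosomal-dominant keratoconus family. The named
    individuals, their affection status, linkage-haplotype labels (L/U),
    sequencing sets (WES/WGS/BOTH) and the genotypes at the two prioritized
    sites (rs35671301 5:103,154,707 T>G; rs373951075 5:96,408,333 G>A)
    follow the published account; the connecting spouses/founders and all
    read depths / qualities are invented. III9 and IV9 carry the linked
    haplotype but are homozygous for the major allele T.

family2.ped / family2_ppip5k2.vcf
    Two-generation family carrying PPIP5K2 c.2528A>G (rs781831998) with
    incomplete penetrance (unaffected carrier parent 201). The genomic
    position 5:103,183,000 is a synthetic placeholder inside the PPIP5K2
    region; only the rsid, HGVS c. notation and MAF are published values.

annotations.tsv       Annotation sidecar for the three fixture variants.
expression_cornea.txt Minimal corneal-expression gene list for the cascade.
locus_narrow.bed      The 95-100 Mb chr5 window (0-based half-open BED).
locus_linkage.bed     The wider chr5q14.3-21.1 linkage window.
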