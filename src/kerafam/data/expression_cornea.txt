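# Genes with expression in human cornea (minimal synthetic list for fixtures)
PPIP5K2
PCSK1
KRT12
ALDH3A1
TGFBI
LUM
KERA
DCN
COL8A2
SLC4A11
CHST6
ZEB1
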