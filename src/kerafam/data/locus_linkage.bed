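5	88699999	102600000	chr5q14.3-21.1_linkage_locus
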