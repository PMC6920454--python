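5	94999999	100000000	narrow_linkage_association_region
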