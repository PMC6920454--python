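"""Annotate the three prioritized coding variants: HGVS parsing, codon
arithmetic, protein consequence, and phosphatase-domain placement.

Run:  python examples/annotate_variants.py
"""

from kerafam.annotation import (
    PPIP5K2_DOMAINS,
    codon_index,
    parse_hgvs_c,
    protein_consequence,
)
from kerafam.transcripts import synthetic_pcsk1_transcript, synthetic_ppip5k2_transcript

TRANSCRIPTS = {
    "PPIP5K2": synthetic_ppip5k2_transcript(),
    "PCSK1": synthetic_pcsk1_transcript(),
}

# Notation as printed in reports varies (spaces, en-dashes); the parser
# accepts the loose dialect and renders the canonical compact form.
VARIANTS = [
    ("PPIP5K2", "c. 1255 T > G"),
    ("PPIP5K2", "c.2528A>G"),
    ("PCSK1", "c.1096-10G>A"),
]

for gene, hgvs in VARIANTS:
    variant = parse_hgvs_c(hgvs)
    consequence = protein_consequence(TRANSCRIPTS[gene], variant)
    line = f"{gene} {variant}: {consequence.consequence_class.value}"
    if consequence.label:
        residue = consequence.residue_index
        domain = PPIP5K2_DOMAINS.lookup(residue) if gene == "PPIP5K2" else "-"
        line += (
            f" {consequence.label} (CDS position {variant.cds_position} -> "
            f"codon {codon_index(variant.cds_position)}; domain: {domain})"
        )
    print(line)

# The two PPIP5K2 missense changes land at residues 419 and 843, both inside
# the phosphatase domain (residues 363-909); the PCSK1 change sits 10 nt
# upstream of an exon acceptor, a splice-proximal intronic variant that only
# a genome-wide (WGS-mode) cascade retains.
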