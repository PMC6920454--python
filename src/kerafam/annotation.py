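"""HGVS coding notation, codon arithmetic, protein consequences, and domains.

Accepts the loose HGVS dialect seen in print (embedded spaces, hyphen or
en-dash for intronic offsets, e.g. ``c. 1255 T > G`` or ``c.1096–10 G > A``)
and always emits the canonical compact form.  Consequence calls use the
standard nuclear genetic code only.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass

from Bio.Seq import Seq
from Bio.SeqUtils import seq1, seq3

from .transcripts import TranscriptModel


class HgvsParseError(ValueError):
    """Malformed HGVS coding notation."""


class ReferenceMismatchError(ValueError):
    """Transcript base does not match the variant's stated reference base."""


class ConsequenceClass(str, enum.Enum):
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    NONSENSE = "nonsense"
    SPLICE_REGION = "splice_region"
    INTRONIC = "intronic"
    OTHER = "other"


#: Intronic variants within this many nt of a splice junction are called
#: splice-proximal.  Wide enough to flag branch-point-adjacent changes such
#: as an acceptor-10 substitution.
DEFAULT_SPLICE_WINDOW = 20

# Dashes that may stand for a negative intronic offset in printed text:
# hyphen-minus, en-dash, em-dash, minus sign.
_DASH = "\\-–—−"
_HGVS_C_RE = re.compile(
    rf"^c\.(\d+)(?:([+{_DASH}])(\d+))?([ACGT])>([ACGT])$"
)


@dataclass(frozen=True)
class CodingHgvs:
    """A single-nucleotide substitution in coding (c.) coordinates.

    ``intron_offset`` is 0 for exonic positions, negative for positions
    upstream of an exon's acceptor site (``c.1096-10``), positive for
    positions downstream of a donor (``c.550+3``).
    """

    cds_position: int
    intron_offset: int
    ref_base: str
    alt_base: str

    def __post_init__(self) -> None:
        if self.cds_position < 1:
            raise HgvsParseError("CDS positions are 1-based; got position < 1")
        for base in (self.ref_base, self.alt_base):
            if base not in "ACGT" or len(base) != 1:
                raise HgvsParseError(f"bad nucleotide {base!r}")
        if self.ref_base == self.alt_base:
            raise HgvsParseError("reference and alternate base are identical")

    @property
    def is_exonic(self) -> bool:
        return self.intron_offset == 0

    def __str__(self) -> str:
        off = ""
        if self.intron_offset > 0:
            off = f"+{self.intron_offset}"
        elif self.intron_offset < 0:
            off = str(self.intron_offset)
        return f"c.{self.cds_position}{off}{self.ref_base}>{self.alt_base}"


def parse_hgvs_c(s: str) -> CodingHgvs:
    """Parse coding-HGVS substitution notation into a :class:`CodingHgvs`.

    >>> parse_hgvs_c("c. 1255 T > G")
    CodingHgvs(cds_position=1255, intron_offset=0, ref_base='T', alt_base='G')
    """
    compact = re.sub(r"\s+", "", s)
    if not compact.startswith("c."):
        raise HgvsParseError(f"not coding-HGVS notation: {s!r}")
    m = _HGVS_C_RE.match(compact)
    if not m:
        raise HgvsParseError(f"cannot parse coding-HGVS substitution: {s!r}")
    pos, sign, offset, ref, alt = m.groups()
    off = 0
    if sign is not None:
        off = int(offset)
        if sign != "+":
            off = -off
    if int(pos) < 1:
        raise HgvsParseError(f"CDS positions are 1-based: {s!r}")
    return CodingHgvs(int(pos), off, ref, alt)


def codon_index(cds_position: int) -> int:
    """1-based codon (residue) number containing a 1-based CDS position."""
    if cds_position < 1:
        raise ValueError("CDS positions are 1-based")
    return (cds_position - 1) // 3 + 1


def codon_offset(cds_position: int) -> int:
    """Position within the codon (0, 1, or 2) of a 1-based CDS position."""
    if cds_position < 1:
        raise ValueError("CDS positions are 1-based")
    return (cds_position - 1) % 3


_LABEL_RE = re.compile(r"^p\.([A-Z][a-z]{2})(\d+)(=|[A-Z][a-z]{2})$")


@dataclass(frozen=True)
class ProteinConsequence:
    """Predicted protein-level consequence of a coding variant.

    For exonic substitutions the residue fields are populated and ``label``
    renders HGVS p. notation (``p.Ser419Ala``; ``p.Ser419=`` when
    synonymous).  Splice-region/intronic calls carry no residue.
    """

    consequence_class: ConsequenceClass
    residue_index: int | None = None
    ref_aa: str | None = None  # one-letter code; "*" for stop
    alt_aa: str | None = None

    @property
    def label(self) -> str | None:
        if self.residue_index is None:
            return None
        ref3 = seq3(self.ref_aa)
        if self.ref_aa == self.alt_aa:
            return f"p.{ref3}{self.residue_index}="
        return f"p.{ref3}{self.residue_index}{seq3(self.alt_aa)}"


def parse_protein_label(label: str) -> tuple[int, str, str]:
    """Parse ``p.Ser419Ala`` / ``p.Ser419=`` into (residue, ref_aa, alt_aa)."""
    m = _LABEL_RE.match(label.strip())
    if not m:
        raise HgvsParseError(f"cannot parse protein label {label!r}")
    ref3, pos, alt3 = m.groups()
    ref = seq1(ref3)
    alt = ref if alt3 == "=" else seq1(alt3)
    return int(pos), ref, alt


def protein_consequence(
    transcript: TranscriptModel,
    variant: CodingHgvs,
    splice_window: int = DEFAULT_SPLICE_WINDOW,
) -> ProteinConsequence:
    """Classify a coding variant against a transcript model.

    Exonic substitutions are translated before/after with the standard
    genetic code; a transcript base differing from the variant's stated
    reference raises :class:`ReferenceMismatchError`.  Intronic variants are
    ``splice_region`` when within ``splice_window`` nt of the junction,
    ``intronic`` otherwise.
    """
    if not variant.is_exonic:
        cls = (
            ConsequenceClass.SPLICE_REGION
            if abs(variant.intron_offset) <= splice_window
            else ConsequenceClass.INTRONIC
        )
        return ProteinConsequence(consequence_class=cls)

    observed = transcript.base(variant.cds_position)
    if observed != variant.ref_base:
        raise ReferenceMismatchError(
            f"{transcript.gene} CDS position {variant.cds_position} is "
            f"{observed}, not the stated reference {variant.ref_base}"
        )
    residue = codon_index(variant.cds_position)
    offset = codon_offset(variant.cds_position)
    ref_codon = transcript.codon(residue)
    alt_codon = ref_codon[:offset] + variant.alt_base + ref_codon[offset + 1 :]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == alt_aa:
        cls = ConsequenceClass.SYNONYMOUS
    elif alt_aa == "*":
        cls = ConsequenceClass.NONSENSE
    elif ref_aa == "*":
        cls = ConsequenceClass.OTHER  # stop-loss; outside the core classes
    else:
        cls = ConsequenceClass.MISSENSE
    return ProteinConsequence(
        consequence_class=cls, residue_index=residue, ref_aa=ref_aa, alt_aa=alt_aa
    )


class DomainMapError(ValueError):
    """Overlapping or unsorted protein-domain intervals."""


class DomainMap:
    """Ordered, non-overlapping protein domains with inclusive residue bounds."""

    def __init__(self, domains: list[tuple[str, int, int]]):
        prev_end = 0
        for name, start, end in domains:
            if start < 1 or end < start:
                raise DomainMapError(f"bad interval for domain {name!r}: [{start}, {end}]")
            if start <= prev_end:
                raise DomainMapError(f"domain {name!r} overlaps its predecessor")
            prev_end = end
        self.domains = list(domains)

    def lookup(self, residue: int) -> str:
        """Name of the domain containing ``residue`` (inclusive), else ``"outside"``."""
        for name, start, end in self.domains:
            if start <= residue <= end:
                return name
        return "outside"

    @classmethod
    def from_tsv(cls, text: str) -> "DomainMap":
        rows = []
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, start, end = line.split("\t")[:3]
            rows.append((name, int(start), int(end)))
        return cls(rows)


def domain_lookup(domain_map: DomainMap, residue: int) -> str:
    return domain_map.lookup(residue)


#: The one PPIP5K2 domain with published residue bounds: the phosphatase
#: domain spans residues 363-909.  Kinase-domain bounds are not defaulted;
#: supply a custom map to add them.
PPIP5K2_DOMAINS = DomainMap([("phosphatase", 363, 909)])
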