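"""Transcript models: a CDS plus exon structure for coding-consequence arithmetic.

Transcripts are read from a CDS FASTA plus a small tab-delimited exon sidecar
(columns: exon index, CDS start, CDS end, 1-based inclusive).  The packaged
PPIP5K2/PCSK1 transcripts are *synthetic*: the published record does not print
the reference codons, so sequences are generated deterministically with the
constraint that the codons touched by the documented variants carry the amino
acids those variants imply (codon 419 = TCT Ser, codon 843 = AAT Asn for
PPIP5K2).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.Seq import Seq


class TranscriptError(ValueError):
    """Invalid transcript model."""


_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class TranscriptModel:
    """A coding sequence with exon structure.

    ``exon_cds_bounds`` gives each exon's span in CDS coordinates (1-based,
    inclusive); intronic HGVS offsets are interpreted relative to these
    junctions.  ``chrom``/``genomic_exon_starts`` optionally anchor the CDS to
    a genome, but none of the consequence arithmetic needs them.
    """

    gene: str
    cds_sequence: str
    strand: str = "+"
    exon_cds_bounds: tuple[tuple[int, int], ...] = ()
    chrom: str | None = None
    genomic_exon_starts: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        seq = self.cds_sequence.upper()
        object.__setattr__(self, "cds_sequence", seq)
        if len(seq) == 0 or len(seq) % 3 != 0:
            raise TranscriptError(
                f"{self.gene}: CDS length {len(seq)} is not a positive multiple of 3"
            )
        if set(seq) - set("ACGT"):
            raise TranscriptError(f"{self.gene}: CDS contains non-ACGT characters")
        protein = str(Seq(seq).translate())
        if "*" in protein[:-1]:
            raise TranscriptError(f"{self.gene}: CDS contains an internal stop codon")
        if self.exon_cds_bounds:
            prev_end = 0
            for start, end in self.exon_cds_bounds:
                if start != prev_end + 1 or end < start:
                    raise TranscriptError(
                        f"{self.gene}: exon CDS bounds must tile the CDS contiguously"
                    )
                prev_end = end
            if prev_end != len(seq):
                raise TranscriptError(
                    f"{self.gene}: exon CDS bounds do not cover the full CDS"
                )

    @property
    def n_codons(self) -> int:
        return len(self.cds_sequence) // 3

    def codon(self, codon_number: int) -> str:
        """The 1-based ``codon_number``-th codon of the CDS."""
        if not 1 <= codon_number <= self.n_codons:
            raise TranscriptError(
                f"{self.gene}: codon {codon_number} outside 1..{self.n_codons}"
            )
        i = (codon_number - 1) * 3
        return self.cds_sequence[i : i + 3]

    def base(self, cds_position: int) -> str:
        """The base at a 1-based CDS position."""
        if not 1 <= cds_position <= len(self.cds_sequence):
            raise TranscriptError(
                f"{self.gene}: CDS position {cds_position} outside "
                f"1..{len(self.cds_sequence)}"
            )
        return self.cds_sequence[cds_position - 1]


def _random_stop_free_codons(n: int, seed: int) -> list[str]:
    rng = np.random.default_rng(seed)
    bases = "ACGT"
    codons: list[str] = []
    while len(codons) < n:
        c = "".join(bases[i] for i in rng.integers(0, 4, size=3))
        if c not in _STOPS:
            codons.append(c)
    return codons


def synthetic_ppip5k2_transcript() -> TranscriptModel:
    """A synthetic 1000-codon PPIP5K2 CDS stand-in.

    Deterministically generated filler sequence with codon 1 = ATG,
    codon 419 = TCT (Ser) and codon 843 = AAT (Asn), so that c.1255T>G yields
    p.Ser419Ala and c.2528A>G yields p.Asn843Ser.  Exon boundaries are placed
    so CDS position 1096 opens an exon (an acceptor site lies 1..N nt
    upstream of it).
    """
    codons = _random_stop_free_codons(1000, seed=20190513)
    codons[0] = "ATG"
    codons[418] = "TCT"  # residue 419, Ser
    codons[842] = "AAT"  # residue 843, Asn
    return TranscriptModel(
        gene="PPIP5K2",
        cds_sequence="".join(codons),
        exon_cds_bounds=((1, 550), (551, 1095), (1096, 1800), (1801, 3000)),
    )


def synthetic_pcsk1_transcript() -> TranscriptModel:
    """A synthetic 800-codon PCSK1 CDS stand-in (see module docstring)."""
    codons = _random_stop_free_codons(800, seed=20190514)
    codons[0] = "ATG"
    return TranscriptModel(
        gene="PCSK1",
        cds_sequence="".join(codons),
        exon_cds_bounds=((1, 1095), (1096, 1700), (1701, 2400)),
    )


def read_transcript(
    fasta_path: str | Path, exons_path: str | Path | None = None, gene: str | None = None
) -> TranscriptModel:
    """Read a transcript from a CDS FASTA plus an optional exon sidecar."""
    from Bio import SeqIO

    record = next(SeqIO.parse(str(fasta_path), "fasta"))
    bounds: list[tuple[int, int]] = []
    if exons_path is not None:
        for line in Path(exons_path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            _, start, end = line.split("\t")[:3]
            bounds.append((int(start), int(end)))
    return TranscriptModel(
        gene=gene or record.id,
        cds_sequence=str(record.seq),
        exon_cds_bounds=tuple(bounds),
    )
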