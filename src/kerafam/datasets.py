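"""Access to the packaged synthetic family fixtures (see ``data/README.txt``)."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .filtering import VariantRecord
from .pedigree import Pedigree, parse_ped
from .vcfio import (
    annotate_records,
    read_annotations,
    read_expression_list,
    read_locus_bed,
    read_vcf,
)


def data_path(name: str) -> Path:
    """Filesystem path of a packaged data file."""
    return Path(resources.files("kerafam.data") / name)


def family1_pedigree() -> Pedigree:
    """The four-generation family with the chr5-linked haplotype."""
    return parse_ped(data_path("family1.ped").read_text())


def family2_pedigree() -> Pedigree:
    """The second, two-generation family (incomplete penetrance)."""
    return parse_ped(data_path("family2.ped").read_text())


def _annotated_vcf(name: str) -> list[VariantRecord]:
    records = read_vcf(data_path(name))
    return annotate_records(records, read_annotations(data_path("annotations.tsv")))


def family1_ppip5k2_records() -> list[VariantRecord]:
    """rs35671301 (5:103,154,707 T>G) genotypes for family 1, annotated."""
    return _annotated_vcf("family1_ppip5k2.vcf")


def family1_pcsk1_records() -> list[VariantRecord]:
    """rs373951075 (5:96,408,333 G>A) genotypes for the WGS samples, annotated."""
    return _annotated_vcf("family1_pcsk1.vcf")


def family2_ppip5k2_records() -> list[VariantRecord]:
    """The second family's PPIP5K2 c.2528A>G genotypes, annotated."""
    return _annotated_vcf("family2_ppip5k2.vcf")


def fixture_annotations() -> pd.DataFrame:
    return read_annotations(data_path("annotations.tsv"))


def corneal_expression_genes() -> frozenset[str]:
    return read_expression_list(data_path("expression_cornea.txt"))


def narrow_locus() -> tuple[str, int, int]:
    """The 95-100 Mb chr5 window, 1-based inclusive."""
    return read_locus_bed(data_path("locus_narrow.bed"))


def linkage_locus() -> tuple[str, int, int]:
    """The wider chr5q14.3-21.1 window, 1-based inclusive."""
    return read_locus_bed(data_path("locus_linkage.bed"))
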