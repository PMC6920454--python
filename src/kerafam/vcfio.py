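"""Readers and writers for the cohort file formats.

* multi-sample VCF 4.2 with GT/DP/GQ (read via pysam; written as plain text
  so simulated fixtures are byte-stable),
* tab-delimited annotation sidecar (variant key, rsid, gene, MAF, HGVS c.,
  consequence class),
* one-gene-per-line corneal expression lists,
* BED locus windows (converted from 0-based half-open to the 1-based
  inclusive convention the filtering module uses throughout).

Multi-allelic VCF rows are split into biallelic records here: for record
``i`` of a split site, sample alleles equal to alt ``i`` become allele 1 and
all other alleles become 0.
"""

from __future__ import annotations


from pathlib import Path

import pandas as pd
import pysam

from .annotation import ConsequenceClass, parse_hgvs_c
from .filtering import GenotypeCall, VariantRecord

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=kerafam
##contig=<ID={contigs}>
##INFO=<ID=RS,Number=1,Type=String,Description="dbSNP identifier">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
"""


def read_vcf(path: str | Path) -> list[VariantRecord]:
    """Read a VCF into biallelic :class:`VariantRecord` objects."""
    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for row in vcf:
            alts = row.alts or ()
            for alt_index, alt in enumerate(alts, start=1):
                calls: dict[str, GenotypeCall] = {}
                for s in samples:
                    sample = row.samples[s]
                    gt = sample.get("GT")
                    if gt is None or any(a is None for a in gt):
                        alleles = None
                    else:
                        alleles = tuple(1 if a == alt_index else 0 for a in gt)
                        if len(alleles) != 2:
                            alleles = None
                    depth = sample.get("DP")
                    quality = sample.get("GQ")
                    calls[s] = GenotypeCall(
                        sample_id=s,
                        alleles=alleles,
                        depth=int(depth) if depth is not None else 0,
                        quality=float(quality) if quality is not None else 0.0,
                    )
                records.append(
                    VariantRecord(
                        chrom=row.chrom,
                        pos=row.pos,
                        ref=row.ref,
                        alt=alt,
                        rsid=None if row.id in (None, ".") else row.id,
                        calls=calls,
                    )
                )
    return records


def write_vcf(
    records: list[VariantRecord], samples: list[str], path: str | Path
) -> None:
    """Write biallelic records as a VCF 4.2 text file with GT:DP:GQ."""
    contigs = sorted({r.chrom for r in records}) or ["5"]
    lines = []
    for contig in contigs:
        lines.append(f"##contig=<ID={contig}>")
    header = _VCF_HEADER.replace(
        "##contig=<ID={contigs}>\n", "\n".join(lines) + "\n" if lines else ""
    )
    out = [header.rstrip("\n")]
    out.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    for r in sorted(records, key=lambda r: (r.chrom, r.pos, r.alt)):
        cols = [
            r.chrom,
            str(r.pos),
            r.rsid or ".",
            r.ref,
            r.alt,
            ".",
            "PASS",
            ".",
            "GT:DP:GQ",
        ]
        for s in samples:
            call = r.call(s)
            if call is None or call.alleles is None:
                gt = "./."
                dp = gq = "."
            else:
                gt = "/".join(str(a) for a in sorted(call.alleles))
                dp = str(int(call.depth))
                gq = str(int(round(call.quality)))
            cols.append(f"{gt}:{dp}:{gq}")
        out.append("\t".join(cols))
    Path(path).write_text("\n".join(out) + "\n")


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read the tab-delimited annotation sidecar keyed by ``chrom:pos:ref:alt``."""
    df = pd.read_csv(path, sep="\t", dtype={"key": str})
    required = {"key", "gene", "maf", "hgvs_c", "consequence_class"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation sidecar missing columns: {sorted(missing)}")
    return df


def write_annotations(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def annotate_records(
    records: list[VariantRecord], annotations: pd.DataFrame
) -> list[VariantRecord]:
    """Attach sidecar annotations to matching records in place (and return them)."""
    by_key = annotations.set_index("key")
    for r in records:
        if r.key not in by_key.index:
            continue
        row = by_key.loc[r.key]
        r.gene = None if pd.isna(row["gene"]) else str(row["gene"])
        maf = row["maf"]
        r.population_maf = None if pd.isna(maf) else float(maf)
        if isinstance(row.get("rsid"), str) and row["rsid"] != ".":
            r.rsid = row["rsid"]
        hgvs = row["hgvs_c"]
        r.hgvs_c = None if pd.isna(hgvs) or hgvs == "." else parse_hgvs_c(str(hgvs))
        cls = row["consequence_class"]
        r.consequence_class = (
            None if pd.isna(cls) or cls == "." else ConsequenceClass(str(cls))
        )
    return records


def read_expression_list(path: str | Path) -> frozenset[str]:
    """Read a one-gene-per-line expression list (comments with ``#``)."""
    genes = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.add(line)
    return frozenset(genes)


def read_locus_bed(path: str | Path) -> tuple[str, int, int]:
    """First interval of a BED file as a 1-based inclusive (chrom, start, end)."""
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        chrom, start, end = line.split("\t")[:3]
        return chrom, int(start) + 1, int(end)
    raise ValueError(f"no intervals in BED file {path}")
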