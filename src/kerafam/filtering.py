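"""Rare-variant prioritization: the ordered filtering cascade and
dominant-model co-segregation scoring.

The cascade applies, in fixed order:

1. sequencing quality / read depth in every sequenced sample,
2. absence of the alternate allele from unaffected controls that do *not*
   carry the disease-linked haplotype (unaffected *linked* carriers are
   penetrance exceptions and never trigger a drop here),
3. population minor-allele frequency at most ``maf_threshold`` (missing MAF
   means a novel variant and is kept),
4. consequence class: exome mode keeps missense/nonsense; genome mode also
   keeps splice-proximal variants and, in corneal-expressed genes,
   intronic/other (regulatory-like) classes,
5. heterozygosity in every affected sequenced sample (dominant model),
6. + 7. gene expressed in human cornea AND position within the linkage locus
   window extended by a symmetric flank.

Counts are conserved at every step and the cascade records a per-step trace.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .annotation import CodingHgvs, ConsequenceClass
from .pedigree import Affection, Haplotype, Pedigree, SeqSet


class FilterConfigError(ValueError):
    """Cascade configuration makes a step meaningless."""


class CascadeError(RuntimeError):
    """A filter step failed; the step name is attached."""


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's call at one site: allele pair, read depth, genotype quality."""

    sample_id: str
    alleles: tuple[int, int] | None  # None = missing call
    depth: int = 0
    quality: float = 0.0

    @property
    def n_alt(self) -> int | None:
        if self.alleles is None:
            return None
        return sum(1 for a in self.alleles if a > 0)

    @property
    def is_het(self) -> bool:
        return self.n_alt == 1

    @property
    def is_hom_ref(self) -> bool:
        return self.alleles is not None and self.n_alt == 0

    @property
    def has_alt(self) -> bool:
        n = self.n_alt
        return n is not None and n > 0


@dataclass
class VariantRecord:
    """One biallelic site with per-sample calls and annotations.

    Multi-allelic VCF rows are split into one record per alternate allele at
    the reader boundary; allele index 1 always means *this* alternate.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    rsid: str | None = None
    population_maf: float | None = None
    gene: str | None = None
    hgvs_c: CodingHgvs | None = None
    consequence_class: ConsequenceClass | None = None
    calls: dict[str, GenotypeCall] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("positions are 1-based")
        if self.population_maf is not None and not 0.0 <= self.population_maf <= 1.0:
            raise ValueError(f"MAF {self.population_maf} outside [0, 1]")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    def call(self, sample_id: str) -> GenotypeCall | None:
        return self.calls.get(sample_id)


class Mode(str, enum.Enum):
    WES = "WES"
    WGS = "WGS"


@dataclass
class FilterConfig:
    """Thresholds and scope for the cascade.

    The published depth criterion reads ">10-20"; the default resolves the
    ambiguity as depth >= 10 with genotype quality >= 20, both configurable.
    ``locus`` is 1-based inclusive; "within/adjacent" the locus is modeled as
    a symmetric ``locus_flank`` (default 2 Mb).
    """

    min_depth: int = 10
    min_quality: float = 20.0
    maf_threshold: float = 0.01
    mode: Mode = Mode.WES
    expression_genes: frozenset[str] = frozenset()
    locus: tuple[str, int, int] | None = None
    locus_flank: int = 2_000_000
    require_het_in_affected: bool = True
    wgs_keep_regulatory: bool = True

    def __post_init__(self) -> None:
        self.mode = Mode(self.mode)
        self.expression_genes = frozenset(self.expression_genes)
        if self.min_depth < 0 or self.min_quality < 0 or self.locus_flank < 0:
            raise FilterConfigError("thresholds must be non-negative")
        if not 0.0 <= self.maf_threshold <= 1.0:
            raise FilterConfigError("maf_threshold must lie in [0, 1]")
        if self.locus is not None and self.locus[1] > self.locus[2]:
            raise FilterConfigError("locus start must be <= end")


@dataclass(frozen=True)
class FilterStep:
    name: str
    n_in: int
    n_out: int
    dropped: tuple[str, ...]  # variant keys

    def __post_init__(self) -> None:
        if self.n_out != self.n_in - len(self.dropped):
            raise ValueError(f"step {self.name}: counts do not conserve")


class FilterTrace:
    """Ordered per-step record of the cascade (input, surviving, dropped keys)."""

    def __init__(self) -> None:
        self.steps: list[FilterStep] = []

    def append(self, step: FilterStep) -> None:
        if self.steps and step.n_in != self.steps[-1].n_out:
            raise ValueError(
                f"step {step.name}: input count {step.n_in} does not match "
                f"prior surviving count {self.steps[-1].n_out}"
            )
        self.steps.append(step)

    def to_tsv(self) -> str:
        lines = ["step\tn_in\tn_out\tn_dropped"]
        for s in self.steps:
            lines.append(f"{s.name}\t{s.n_in}\t{s.n_out}\t{len(s.dropped)}")
        return "\n".join(lines) + "\n"

    def __str__(self) -> str:
        return "\n".join(
            f"{s.name}: {s.n_in} -> {s.n_out} ({len(s.dropped)} dropped)"
            for s in self.steps
        )


def _selected_samples(pedigree: Pedigree, cfg: FilterConfig) -> list[str]:
    mode = SeqSet.WES if cfg.mode is Mode.WES else SeqSet.WGS
    samples = pedigree.selected(mode)
    if not samples:
        raise FilterConfigError(
            f"no samples in the {cfg.mode.value} analysis set of the pedigree"
        )
    return samples


def _split(records, keep) -> tuple[list[VariantRecord], list[str]]:
    kept, dropped = [], []
    for r in records:
        (kept if keep(r) else dropped).append(r)
    return kept, [r.key for r in dropped]


def filter_qc(
    records: list[VariantRecord], pedigree: Pedigree, cfg: FilterConfig
) -> tuple[list[VariantRecord], FilterStep]:
    """Criterion 1: depth and genotype quality in every sequenced sample.

    Missing calls in any sequenced sample fail the record (survivors of the
    published cascade were fully genotyped).
    """
    samples = _selected_samples(pedigree, cfg)

    def ok(record: VariantRecord) -> bool:
        for s in samples:
            call = record.call(s)
            if call is None or call.alleles is None:
                return False
            if call.depth < cfg.min_depth or call.quality < cfg.min_quality:
                return False
        return True

    kept, dropped = _split(records, ok)
    return kept, FilterStep("quality_depth", len(records), len(kept), tuple(dropped))


def filter_control_absence(
    records: list[VariantRecord], pedigree: Pedigree, cfg: FilterConfig
) -> tuple[list[VariantRecord], FilterStep]:
    """Criterion 2: alt allele absent from unaffected, explicitly-unlinked controls."""
    samples = _selected_samples(pedigree, cfg)
    controls = [
        s
        for s in samples
        if pedigree[s].affected is Affection.UNAFFECTED
        and pedigree[s].haplotype is Haplotype.UNLINKED
    ]

    def ok(record: VariantRecord) -> bool:
        for s in controls:
            call = record.call(s)
            if call is not None and call.has_alt:
                return False
        return True

    kept, dropped = _split(records, ok)
    return kept, FilterStep("control_absence", len(records), len(kept), tuple(dropped))


def filter_maf(
    records: list[VariantRecord], cfg: FilterConfig
) -> tuple[list[VariantRecord], FilterStep]:
    """Criterion 3: population MAF <= threshold; missing MAF = novel, kept."""

    def ok(record: VariantRecord) -> bool:
        return record.population_maf is None or record.population_maf <= cfg.maf_threshold

    kept, dropped = _split(records, ok)
    return kept, FilterStep("maf", len(records), len(kept), tuple(dropped))


_WES_CLASSES = {ConsequenceClass.MISSENSE, ConsequenceClass.NONSENSE}
_WGS_EXTRA = {ConsequenceClass.SPLICE_REGION}
_WGS_REGULATORY = {ConsequenceClass.INTRONIC, ConsequenceClass.OTHER}


def filter_consequence(
    records: list[VariantRecord], cfg: FilterConfig
) -> tuple[list[VariantRecord], FilterStep]:
    """Criterion 4: coding non-synonymous (exome); genome mode is broader."""

    def ok(record: VariantRecord) -> bool:
        cls = record.consequence_class
        if cls is None:
            return False
        cls = ConsequenceClass(cls)
        if cls in _WES_CLASSES:
            return True
        if cfg.mode is Mode.WGS:
            if cls in _WGS_EXTRA:
                return True
            if (
                cfg.wgs_keep_regulatory
                and cls in _WGS_REGULATORY
                and record.gene in cfg.expression_genes
            ):
                return True
        return False

    kept, dropped = _split(records, ok)
    return kept, FilterStep("consequence", len(records), len(kept), tuple(dropped))


def filter_affected_het(
    records: list[VariantRecord], pedigree: Pedigree, cfg: FilterConfig
) -> tuple[list[VariantRecord], FilterStep]:
    """Criterion 5: heterozygous in every affected sequenced sample (dominant model)."""
    samples = _selected_samples(pedigree, cfg)
    affected = [s for s in samples if pedigree[s].affected is Affection.AFFECTED]

    def ok(record: VariantRecord) -> bool:
        if not cfg.require_het_in_affected:
            return True
        for s in affected:
            call = record.call(s)
            if call is None or not call.is_het:
                return False
        return True

    kept, dropped = _split(records, ok)
    return kept, FilterStep("affected_het", len(records), len(kept), tuple(dropped))


def _norm_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def filter_expression_and_locus(
    records: list[VariantRecord], cfg: FilterConfig
) -> tuple[list[VariantRecord], FilterStep]:
    """Criteria 6+7: corneal-expressed gene AND inside the flanked locus window."""
    if cfg.locus is None:
        raise FilterConfigError("locus window is required for the locus criterion")
    chrom, start, end = cfg.locus
    lo = max(1, start - cfg.locus_flank)
    hi = end + cfg.locus_flank

    def ok(record: VariantRecord) -> bool:
        if record.gene not in cfg.expression_genes:
            return False
        return _norm_chrom(record.chrom) == _norm_chrom(chrom) and lo <= record.pos <= hi

    kept, dropped = _split(records, ok)
    return kept, FilterStep(
        "expression_and_locus", len(records), len(kept), tuple(dropped)
    )


def run_cascade(
    records: list[VariantRecord], pedigree: Pedigree, cfg: FilterConfig
) -> tuple[list[VariantRecord], FilterTrace]:
    """Apply all criteria in the fixed published order, recording a trace."""
    trace = FilterTrace()
    current = list(records)
    steps = (
        ("quality_depth", lambda r: filter_qc(r, pedigree, cfg)),
        ("control_absence", lambda r: filter_control_absence(r, pedigree, cfg)),
        ("maf", lambda r: filter_maf(r, cfg)),
        ("consequence", lambda r: filter_consequence(r, cfg)),
        ("affected_het", lambda r: filter_affected_het(r, pedigree, cfg)),
        ("expression_and_locus", lambda r: filter_expression_and_locus(r, cfg)),
    )
    for name, fn in steps:
        try:
            current, step = fn(current)
        except FilterConfigError:
            raise
        except Exception as exc:  # attach the step name
            raise CascadeError(f"step {name!r} failed: {exc}") from exc
        trace.append(step)
    return current, trace


# ---------------------------------------------------------------------------
# Co-segregation scoring
# ---------------------------------------------------------------------------


@dataclass
class SegregationReport:
    """Dominant-model co-segregation classification for one variant.

    Individuals are scored only when genotype, affection, and haplotype are
    all known; others land in ``unscored``.  ``penetrance_estimate`` is
    affected variant-carriers over all variant-carriers among the scored
    individuals (``None`` when no carriers were scored).
    """

    variant_key: str
    consistent: list[str] = field(default_factory=list)
    carrier_without_variant: list[str] = field(default_factory=list)
    variant_without_haplotype: list[str] = field(default_factory=list)
    affected_noncarriers_with_variant: list[str] = field(default_factory=list)
    unscored: list[str] = field(default_factory=list)
    penetrance_estimate: float | None = None

    @property
    def n_scored(self) -> int:
        return (
            len(self.consistent)
            + len(self.carrier_without_variant)
            + len(self.variant_without_haplotype)
            + len(self.affected_noncarriers_with_variant)
        )

    def summary(self) -> str:
        lines = [
            f"variant {self.variant_key}: {len(self.consistent)} consistent "
            f"of {self.n_scored} scored",
        ]
        if self.carrier_without_variant:
            lines.append(
                "haplotype carriers without the variant: "
                + ", ".join(self.carrier_without_variant)
            )
        if self.variant_without_haplotype:
            lines.append(
                "variant carriers without the haplotype: "
                + ", ".join(self.variant_without_haplotype)
            )
        if self.affected_noncarriers_with_variant:
            lines.append(
                "affected haplotype non-carriers with the variant: "
                + ", ".join(self.affected_noncarriers_with_variant)
            )
        if self.penetrance_estimate is not None:
            lines.append(f"penetrance estimate: {self.penetrance_estimate:.3f}")
        return "\n".join(lines)


def segregation_report(
    record: VariantRecord,
    pedigree: Pedigree,
    samples: list[str] | None = None,
) -> SegregationReport:
    """Score dominant-model co-segregation of one variant with the haplotype.

    Classification, in priority order per individual:

    * linked haplotype but homozygous major  -> ``carrier_without_variant``
    * carries the variant but not the linked haplotype -> split into
      ``affected_noncarriers_with_variant`` / ``variant_without_haplotype``
      by affection,
    * affected + linked + heterozygous, or unaffected + unlinked +
      homozygous major -> ``consistent``,
    * everything else (e.g. unaffected linked heterozygote, a pure
      penetrance exception) -> ``unscored``.
    """
    ids = samples if samples is not None else [i for i in record.calls]
    report = SegregationReport(variant_key=record.key)
    n_carriers = 0
    n_affected_carriers = 0
    for sample_id in ids:
        ind = pedigree[sample_id]
        call = record.call(sample_id)
        if (
            call is None
            or call.alleles is None
            or ind.affected is Affection.UNKNOWN
            or ind.haplotype is Haplotype.UNKNOWN
        ):
            report.unscored.append(sample_id)
            continue
        linked = ind.haplotype is Haplotype.LINKED
        affected = ind.affected is Affection.AFFECTED
        if call.has_alt:
            n_carriers += 1
            if affected:
                n_affected_carriers += 1
        if linked and call.is_hom_ref:
            report.carrier_without_variant.append(sample_id)
        elif not linked and call.has_alt:
            if affected:
                report.affected_noncarriers_with_variant.append(sample_id)
            else:
                report.variant_without_haplotype.append(sample_id)
        elif affected and linked and call.is_het:
            report.consistent.append(sample_id)
        elif not affected and not linked and call.is_hom_ref:
            report.consistent.append(sample_id)
        else:
            report.unscored.append(sample_id)
    if report.n_scored == 0:
        import warnings

        warnings.warn(
            f"no scorable individuals for variant {record.key}", stacklevel=2
        )
    if n_carriers > 0:
        report.penetrance_estimate = n_affected_carriers / n_carriers
    return report
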