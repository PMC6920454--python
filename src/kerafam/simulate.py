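"""Synthetic familial cohorts for exercising the filtering cascade.

Simulates the statistical structure a dominant-model prioritization assumes:
a founder disease haplotype gene-dropped through a multi-generation
pedigree, one spiked causal variant riding that haplotype (recombination
fraction 0 by default — the locus is Mb-scale and the pedigree shallow),
configurable penetrance and phenocopy rate, independent background variants
with Hardy-Weinberg founder genotypes, and negative-binomial read depths
echoing deep exome coverage (mean 75x by default).

All randomness flows from one master seed through named substreams, so each
stage is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import ConsequenceClass, parse_hgvs_c
from .filtering import FilterConfig, GenotypeCall, VariantRecord
from .pedigree import Affection, Haplotype, Pedigree, SeqSet
from .vcfio import write_annotations, write_vcf

_STAGES = {"gene_drop": 1, "affection": 2, "background": 3, "depth": 4, "noise": 5}


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), _STAGES[stage]])


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class CausalSpec:
    """Where the spiked causal variant lives and how it is annotated."""

    chrom: str = "5"
    pos: int = 103_154_707
    ref: str = "T"
    alt: str = "G"
    gene: str = "PPIP5K2"
    hgvs_c: str = "c.1255T>G"
    maf: float = 0.0069
    consequence_class: ConsequenceClass = ConsequenceClass.MISSENSE


@dataclass
class GenomicSimParams:
    """Knobs of the cohort simulator; defaults mirror the study design.

    ``background_maf_beta`` parameterizes a right-skewed Beta law for
    background-variant population frequencies.  ``depth_mean``/``depth_size``
    are negative-binomial parameters (mean 75 echoes deep exome coverage).
    Gene drops are ascertainment-conditioned: draws are rejected until the
    sequenced samples contain at least ``min_affected_selected`` affecteds
    and one unaffected-unlinked control, mirroring how multiplex disease
    families enter a study in the first place.
    """

    pedigree: Pedigree
    founder_id: str = "I1"
    causal: CausalSpec = field(default_factory=CausalSpec)
    penetrance: float = 1.0
    phenocopy_rate: float = 0.0
    n_background: int = 500
    background_maf_beta: tuple[float, float] = (0.5, 5.0)
    depth_mean: float = 75.0
    depth_size: float = 30.0
    quality_mean: float = 60.0
    quality_sd: float = 8.0
    genotype_error_rate: float = 0.0
    recombination_fraction: float = 0.0
    min_affected_selected: int = 3
    expression_genes: tuple[str, ...] = (
        "PPIP5K2",
        "PCSK1",
        "KRT12",
        "ALDH3A1",
        "TGFBI",
        "LUM",
        "KERA",
        "DCN",
    )
    mode: str = "WES"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("penetrance", "phenocopy_rate", "genotype_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 <= self.recombination_fraction <= 0.5:
            raise SimulationError("recombination_fraction must lie in [0, 0.5]")
        if self.n_background < 0:
            raise SimulationError("n_background must be >= 0")


def gene_drop(
    pedigree: Pedigree,
    founder_id: str,
    seed: int | np.random.Generator = 0,
) -> dict[str, bool]:
    """Drop a single founder haplotype through the pedigree.

    The named founder carries the linked haplotype on one homolog; every
    offspring of a carrier inherits it with probability 1/2, independently
    per meiosis.  Returns carrier status per individual id.
    """
    founder = pedigree[founder_id]
    if not founder.is_founder:
        raise SimulationError(f"{founder_id!r} is not a founder of the pedigree")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    carries: dict[str, bool] = {}
    for ind in pedigree.topological_order():
        if ind.is_founder:
            carries[ind.id] = ind.id == founder_id
            continue
        inherited = False
        for parent_id in (ind.father_id, ind.mother_id):
            if carries[parent_id] and rng.random() < 0.5:
                inherited = True
        carries[ind.id] = inherited
    return carries


def _drop_two_locus(
    pedigree: Pedigree,
    founder_id: str,
    recombination_fraction: float,
    rng: np.random.Generator,
) -> tuple[dict[str, bool], dict[str, bool]]:
    """Joint drop of (haplotype label, causal allele) on the same founder homolog.

    Each individual holds two homologs, each a (haplotype, variant) pair;
    a gamete copies one homolog, swapping the variant locus between homologs
    with probability ``recombination_fraction``.
    """
    homologs: dict[str, list[tuple[bool, bool]]] = {}
    for ind in pedigree.topological_order():
        if ind.is_founder:
            first = (True, True) if ind.id == founder_id else (False, False)
            homologs[ind.id] = [first, (False, False)]
            continue
        gametes = []
        for parent_id in (ind.father_id, ind.mother_id):
            pair = homologs[parent_id]
            which = int(rng.random() < 0.5)
            hap, var = pair[which]
            if rng.random() < recombination_fraction:
                var = pair[1 - which][1]
            gametes.append((hap, var))
        homologs[ind.id] = gametes
    hap = {i: h[0][0] or h[1][0] for i, h in homologs.items()}
    var = {i: h[0][1] or h[1][1] for i, h in homologs.items()}
    return hap, var


@dataclass
class SimulatedCohort:
    """Output bundle of :func:`simulate_cohort`."""

    records: list[VariantRecord]
    pedigree: Pedigree  # statuses filled in
    causal_key: str
    carriers: frozenset[str]  # causal-variant carriers
    truth: pd.DataFrame  # per-individual: haplotype carrier, variant carrier, affected
    annotations: pd.DataFrame

    def filter_config(self, **overrides) -> FilterConfig:
        """A FilterConfig matching the simulated study design."""
        defaults = dict(
            expression_genes=frozenset(self.annotations.attrs["expression_genes"]),
            locus=tuple(self.annotations.attrs["locus"]),
            mode=self.annotations.attrs["mode"],
        )
        defaults.update(overrides)
        return FilterConfig(**defaults)


_BACKGROUND_CLASSES = (
    ConsequenceClass.MISSENSE,
    ConsequenceClass.SYNONYMOUS,
    ConsequenceClass.INTRONIC,
    ConsequenceClass.SPLICE_REGION,
    ConsequenceClass.NONSENSE,
)
_BACKGROUND_CLASS_P = np.array([0.25, 0.25, 0.40, 0.05, 0.05])
#: Simulated linkage window (1-based inclusive) used for the locus criterion.
DEFAULT_LOCUS = ("5", 88_700_000, 102_600_000)


def simulate_cohort(params: GenomicSimParams) -> SimulatedCohort:
    """Simulate one familial cohort with a spiked causal variant.

    Returns records carrying per-sample GT/DP/GQ for every pedigree member,
    a pedigree with simulated affection and haplotype labels, and a truth
    table of carrier status.
    """
    ped = params.pedigree
    if params.founder_id not in ped:
        raise SimulationError(f"founder {params.founder_id!r} not in pedigree")
    if not ped[params.founder_id].is_founder:
        raise SimulationError(f"{params.founder_id!r} is not a founder")
    mode = SeqSet.WES if params.mode.upper() == "WES" else SeqSet.WGS
    selected = ped.selected(mode)
    if not selected:
        raise SimulationError(f"pedigree has no {params.mode} samples")

    drop_rng = _stage_rng(params.seed, "gene_drop")
    aff_rng = _stage_rng(params.seed, "affection")
    for _attempt in range(10_000):
        hap, var = _drop_two_locus(
            ped, params.founder_id, params.recombination_fraction, drop_rng
        )
        affected = {
            i: bool(
                aff_rng.random()
                < (params.penetrance if var[i] else params.phenocopy_rate)
            )
            for i in ped.ids
        }
        n_aff = sum(affected[s] for s in selected)
        n_ctrl = sum((not affected[s]) and (not hap[s]) for s in selected)
        if n_aff >= params.min_affected_selected and n_ctrl >= 1:
            break
    else:  # pragma: no cover
        raise SimulationError("ascertainment rejection did not converge")

    ped2 = ped.with_statuses(
        affected={
            i: Affection.AFFECTED if affected[i] else Affection.UNAFFECTED
            for i in ped.ids
        },
        haplotype={
            i: Haplotype.LINKED if hap[i] else Haplotype.UNLINKED for i in ped.ids
        },
    )

    ids = ped.ids
    n_ind = len(ids)
    order = [ind.id for ind in ped.topological_order()]
    idx = {i: k for k, i in enumerate(ids)}

    # Background variants: HWE founder genotypes dropped independently.
    bg_rng = _stage_rng(params.seed, "background")
    n_bg = params.n_background
    a, b = params.background_maf_beta
    mafs = bg_rng.beta(a, b, size=n_bg)
    positions = bg_rng.integers(1, 180_000_000, size=n_bg)
    expressed = bg_rng.random(n_bg) < 0.5
    gene_ix = bg_rng.integers(0, len(params.expression_genes), size=n_bg)
    classes = bg_rng.choice(len(_BACKGROUND_CLASSES), size=n_bg, p=_BACKGROUND_CLASS_P)
    genotypes = np.zeros((n_ind, n_bg, 2), dtype=np.int8)
    for ind_id in order:
        ind = ped[ind_id]
        k = idx[ind_id]
        if ind.is_founder:
            genotypes[k] = (bg_rng.random((n_bg, 2)) < mafs[:, None]).astype(np.int8)
        else:
            for slot, parent_id in enumerate((ind.father_id, ind.mother_id)):
                p = genotypes[idx[parent_id]]
                pick = bg_rng.integers(0, 2, size=n_bg)
                genotypes[k, :, slot] = p[np.arange(n_bg), pick]

    # Depths, qualities, genotyping noise.
    depth_rng = _stage_rng(params.seed, "depth")
    noise_rng = _stage_rng(params.seed, "noise")
    n_sites = n_bg + 1
    p_nb = params.depth_size / (params.depth_size + params.depth_mean)
    depths = depth_rng.negative_binomial(params.depth_size, p_nb, size=(n_ind, n_sites))
    quals = np.clip(
        depth_rng.normal(params.quality_mean, params.quality_sd, size=(n_ind, n_sites)),
        0.0,
        99.0,
    )

    causal = params.causal
    causal_alleles = {
        i: (0, 1) if var[i] else (0, 0) for i in ids
    }  # het on the dropped homolog

    def apply_noise(alleles: tuple[int, int]) -> tuple[int, int]:
        if params.genotype_error_rate > 0 and noise_rng.random() < params.genotype_error_rate:
            slot = int(noise_rng.integers(0, 2))
            flipped = list(alleles)
            flipped[slot] = 1 - flipped[slot]
            return tuple(flipped)
        return alleles

    records: list[VariantRecord] = []
    ann_rows: list[dict] = []

    causal_calls = {
        i: GenotypeCall(
            sample_id=i,
            alleles=apply_noise(causal_alleles[i]),
            depth=int(depths[idx[i], 0]),
            quality=float(quals[idx[i], 0]),
        )
        for i in ids
    }
    causal_rec = VariantRecord(
        chrom=causal.chrom,
        pos=causal.pos,
        ref=causal.ref,
        alt=causal.alt,
        population_maf=causal.maf,
        gene=causal.gene,
        hgvs_c=parse_hgvs_c(causal.hgvs_c),
        consequence_class=causal.consequence_class,
        calls=causal_calls,
    )
    records.append(causal_rec)
    ann_rows.append(
        dict(
            key=causal_rec.key,
            rsid=".",
            gene=causal.gene,
            maf=causal.maf,
            hgvs_c=causal.hgvs_c,
            consequence_class=causal.consequence_class.value,
        )
    )

    bases = np.array(list("ACGT"))
    ref_ix = bg_rng.integers(0, 4, size=n_bg)
    alt_ix = (ref_ix + bg_rng.integers(1, 4, size=n_bg)) % 4
    for j in range(n_bg):
        gene = (
            params.expression_genes[gene_ix[j]]
            if expressed[j]
            else f"BGGENE{j:04d}"
        )
        calls = {
            i: GenotypeCall(
                sample_id=i,
                alleles=apply_noise(tuple(int(x) for x in genotypes[idx[i], j])),
                depth=int(depths[idx[i], j + 1]),
                quality=float(quals[idx[i], j + 1]),
            )
            for i in ids
        }
        rec = VariantRecord(
            chrom="5",
            pos=int(positions[j]),
            ref=str(bases[ref_ix[j]]),
            alt=str(bases[alt_ix[j]]),
            population_maf=float(mafs[j]),
            gene=gene,
            consequence_class=_BACKGROUND_CLASSES[classes[j]],
            calls=calls,
        )
        records.append(rec)
        ann_rows.append(
            dict(
                key=rec.key,
                rsid=".",
                gene=gene,
                maf=float(mafs[j]),
                hgvs_c=".",
                consequence_class=rec.consequence_class.value,
            )
        )

    truth = pd.DataFrame(
        {
            "individual": ids,
            "haplotype_carrier": [hap[i] for i in ids],
            "variant_carrier": [var[i] for i in ids],
            "affected": [affected[i] for i in ids],
        }
    )
    annotations = pd.DataFrame(ann_rows)
    annotations.attrs["expression_genes"] = list(params.expression_genes)
    annotations.attrs["locus"] = DEFAULT_LOCUS
    annotations.attrs["mode"] = params.mode
    return SimulatedCohort(
        records=records,
        pedigree=ped2,
        causal_key=causal_rec.key,
        carriers=frozenset(i for i in ids if var[i]),
        truth=truth,
        annotations=annotations,
    )


def write_fixture(cohort: SimulatedCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write VCF 4.2 + PED + annotation sidecar + truth table, byte-stable."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "cohort.vcf",
        "ped": out / "cohort.ped",
        "annotations": out / "annotations.tsv",
        "truth": out / "truth.tsv",
    }
    write_vcf(cohort.records, cohort.pedigree.ids, paths["vcf"])
    paths["ped"].write_text(cohort.pedigree.write_ped())
    write_annotations(cohort.annotations, paths["annotations"])
    cohort.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
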