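"""The seven-criterion cascade and co-segregation scoring."""

import random

import pytest

from kerafam import datasets
from kerafam.annotation import ConsequenceClass
from kerafam.filtering import (
    FilterConfig,
    FilterConfigError,
    FilterStep,
    FilterTrace,
    GenotypeCall,
    Mode,
    VariantRecord,
    filter_affected_het,
    filter_consequence,
    filter_control_absence,
    filter_expression_and_locus,
    filter_maf,
    filter_qc,
    run_cascade,
    segregation_report,
)
from kerafam.pedigree import Affection, Haplotype, SeqSet, parse_ped

# ---------------------------------------------------------------------------
# Independent brute-force oracle: one conjunction of the seven criteria,
# evaluated per record, written without reference to the cascade code.
# ---------------------------------------------------------------------------


def brute_force_survivors(records, ped, cfg):
    mode = SeqSet.WES if Mode(cfg.mode) is Mode.WES else SeqSet.WGS
    samples = [
        i.id for i in ped if i.sequenced in (mode, SeqSet.BOTH)
    ]
    affected = [s for s in samples if ped[s].affected is Affection.AFFECTED]
    controls = [
        s
        for s in samples
        if ped[s].affected is Affection.UNAFFECTED
        and ped[s].haplotype is Haplotype.UNLINKED
    ]
    chrom, start, end = cfg.locus
    keep = []
    for r in records:
        calls = {s: r.calls.get(s) for s in samples}
        if any(c is None or c.alleles is None for c in calls.values()):
            continue
        if any(
            c.depth < cfg.min_depth or c.quality < cfg.min_quality
            for c in calls.values()
        ):
            continue
        if any(sum(a > 0 for a in calls[s].alleles) > 0 for s in controls):
            continue
        if r.population_maf is not None and r.population_maf > cfg.maf_threshold:
            continue
        cls = r.consequence_class
        coding = cls in (ConsequenceClass.MISSENSE, ConsequenceClass.NONSENSE)
        if Mode(cfg.mode) is Mode.WES:
            if not coding:
                continue
        else:
            relaxed = coding or cls is ConsequenceClass.SPLICE_REGION or (
                cls in (ConsequenceClass.INTRONIC, ConsequenceClass.OTHER)
                and r.gene in cfg.expression_genes
            )
            if not relaxed:
                continue
        if any(sum(a > 0 for a in calls[s].alleles) != 1 for s in affected):
            continue
        if r.gene not in cfg.expression_genes:
            continue
        if r.chrom != chrom or not (
            start - cfg.locus_flank <= r.pos <= end + cfg.locus_flank
        ):
            continue
        keep.append(r.key)
    return keep


# ---------------------------------------------------------------------------
# Small hand-built cohort helpers
# ---------------------------------------------------------------------------

MINI_PED = """
F A1 0 0 1 2 L WES
F U1 0 0 2 1 U WES
F C1 0 0 2 1 L WES
"""


@pytest.fixture
def mini_ped():
    return parse_ped(MINI_PED)


def make_record(pos=96_500_000, gene="PPIP5K2", maf=0.001,
                cls=ConsequenceClass.MISSENSE, calls=None, **kwargs):
    default_calls = {
        "A1": GenotypeCall("A1", (0, 1), depth=60, quality=80),
        "U1": GenotypeCall("U1", (0, 0), depth=60, quality=80),
        "C1": GenotypeCall("C1", (0, 0), depth=60, quality=80),
    }
    return VariantRecord(
        chrom="5", pos=pos, ref="T", alt="G", population_maf=maf, gene=gene,
        consequence_class=cls, calls=calls or default_calls, **kwargs,
    )


@pytest.fixture
def mini_cfg():
    return FilterConfig(
        expression_genes=frozenset({"PPIP5K2", "PCSK1"}),
        locus=("5", 88_700_000, 102_600_000),
    )


def set_call(record, sample, alleles=None, depth=60, quality=80):
    record.calls[sample] = GenotypeCall(sample, alleles, depth, quality)
    return record


# ---------------------------------------------------------------------------
# Individual criteria
# ---------------------------------------------------------------------------


def test_qc_drops_shallow_depth(mini_ped, mini_cfg):
    low = set_call(make_record(), "A1", (0, 1), depth=5)
    good = make_record()
    kept, step = filter_qc([low, good], mini_ped, mini_cfg)
    assert [r.key for r in kept] == [good.key]
    assert step.n_in == 2 and step.n_out == 1


def test_qc_missing_call_fails_strictly(mini_ped, mini_cfg):
    rec = set_call(make_record(), "U1", None)
    kept, _ = filter_qc([rec], mini_ped, mini_cfg)
    assert kept == []


def test_qc_requires_nonempty_sample_set(mini_cfg):
    ped = parse_ped("F X 0 0 1 2 L NONE")
    with pytest.raises(FilterConfigError):
        filter_qc([make_record()], ped, mini_cfg)


def test_control_absence_drops_unlinked_control_carrier(mini_ped, mini_cfg):
    rec = set_call(make_record(), "U1", (0, 1))
    kept, _ = filter_control_absence([rec], mini_ped, mini_cfg)
    assert kept == []


def test_control_absence_spares_linked_unaffected_carrier(mini_ped, mini_cfg):
    # C1 is unaffected but carries the linked haplotype: a penetrance
    # exception, not a control — the record must survive.
    rec = set_call(make_record(), "C1", (0, 1))
    kept, _ = filter_control_absence([rec], mini_ped, mini_cfg)
    assert len(kept) == 1


def test_control_absence_keeps_affected_only_variants(mini_ped, mini_cfg):
    kept, _ = filter_control_absence([make_record()], mini_ped, mini_cfg)
    assert len(kept) == 1


@pytest.mark.parametrize(
    "maf, kept", [(0.0069, True), (0.01, True), (0.02, False), (None, True)]
)
def test_maf_threshold_boundary(mini_cfg, maf, kept):
    out, _ = filter_maf([make_record(maf=maf)], mini_cfg)
    assert bool(out) is kept


def test_consequence_wes_vs_wgs_for_splice_region(mini_ped, mini_cfg):
    splice = make_record(cls=ConsequenceClass.SPLICE_REGION, gene="PCSK1")
    out_wes, _ = filter_consequence([splice], mini_cfg)
    assert out_wes == []
    wgs_cfg = FilterConfig(
        mode="WGS", expression_genes=mini_cfg.expression_genes, locus=mini_cfg.locus
    )
    out_wgs, _ = filter_consequence([splice], wgs_cfg)
    assert len(out_wgs) == 1


@pytest.mark.parametrize("mode", ["WES", "WGS"])
def test_consequence_synonymous_always_dropped(mini_cfg, mode):
    cfg = FilterConfig(mode=mode, expression_genes=mini_cfg.expression_genes,
                       locus=mini_cfg.locus)
    out, _ = filter_consequence([make_record(cls=ConsequenceClass.SYNONYMOUS)], cfg)
    assert out == []


def test_consequence_missense_kept(mini_cfg):
    out, _ = filter_consequence([make_record()], mini_cfg)
    assert len(out) == 1


def test_affected_het_rejects_hom_alt_and_missing(mini_ped, mini_cfg):
    hom = set_call(make_record(), "A1", (1, 1))
    missing = set_call(make_record(), "A1", None)
    good = make_record()
    kept, _ = filter_affected_het([hom, missing, good], mini_ped, mini_cfg)
    assert [r.key for r in kept] == [good.key]


def test_locus_narrow_vs_extended_window(mini_cfg):
    narrow = FilterConfig(
        expression_genes=mini_cfg.expression_genes,
        locus=("5", 95_000_000, 100_000_000),
        locus_flank=0,
    )
    pcsk1 = make_record(pos=96_408_333, gene="PCSK1")
    ppip5k2 = make_record(pos=103_154_707, gene="PPIP5K2")
    kept, _ = filter_expression_and_locus([pcsk1, ppip5k2], narrow)
    assert [r.key for r in kept] == [pcsk1.key]
    # extending the window to the original linkage peak recovers the second
    extended = FilterConfig(
        expression_genes=mini_cfg.expression_genes,
        locus=("5", 95_000_000, 103_200_000),
        locus_flank=0,
    )
    kept2, _ = filter_expression_and_locus([pcsk1, ppip5k2], extended)
    assert len(kept2) == 2


def test_locus_requires_expression_listed_gene(mini_cfg):
    rec = make_record(gene="NOTCORNEA")
    kept, _ = filter_expression_and_locus([rec], mini_cfg)
    assert kept == []


# ---------------------------------------------------------------------------
# Cascade properties
# ---------------------------------------------------------------------------


def test_trace_conservation_and_step_arithmetic():
    with pytest.raises(ValueError):
        FilterStep("bad", 100, 93, dropped=tuple(f"k{i}" for i in range(5)))
    trace = FilterTrace()
    trace.append(FilterStep("a", 100, 93, tuple(f"k{i}" for i in range(7))))
    with pytest.raises(ValueError):
        trace.append(FilterStep("b", 90, 90, ()))


def test_cascade_empty_input_gives_zero_trace(mini_ped, mini_cfg):
    out, trace = run_cascade([], mini_ped, mini_cfg)
    assert out == []
    assert all(s.n_in == 0 and s.n_out == 0 for s in trace.steps)
    assert len(trace.steps) == 6


def test_cascade_maf_zero_keeps_only_novel(mini_ped, mini_cfg):
    cfg = FilterConfig(
        maf_threshold=0.0,
        expression_genes=mini_cfg.expression_genes,
        locus=mini_cfg.locus,
    )
    novel = make_record(maf=None)
    rare = make_record(pos=96_500_001, maf=1e-5)
    out, _ = run_cascade([novel, rare], mini_ped, cfg)
    assert [r.key for r in out] == [novel.key]


def test_cascade_totals_conserve_and_match_oracle(family1):
    from kerafam.simulate import GenomicSimParams, simulate_cohort

    for seed in range(5):
        cohort = simulate_cohort(
            GenomicSimParams(pedigree=family1, n_background=40, seed=seed)
        )
        cfg = cohort.filter_config()
        out, trace = run_cascade(cohort.records, cohort.pedigree, cfg)
        assert trace.steps[0].n_in == len(cohort.records)
        dropped = sum(len(s.dropped) for s in trace.steps)
        assert dropped + len(out) == len(cohort.records)
        assert [r.key for r in out] == brute_force_survivors(
            cohort.records, cohort.pedigree, cfg
        )


def test_cascade_invariant_to_record_order(family1):
    from kerafam.simulate import GenomicSimParams, simulate_cohort

    cohort = simulate_cohort(
        GenomicSimParams(pedigree=family1, n_background=60, seed=11)
    )
    cfg = cohort.filter_config()
    out1, _ = run_cascade(cohort.records, cohort.pedigree, cfg)
    shuffled = cohort.records.copy()
    random.Random(7).shuffle(shuffled)
    out2, _ = run_cascade(shuffled, cohort.pedigree, cfg)
    assert {r.key for r in out1} == {r.key for r in out2}


# ---------------------------------------------------------------------------
# Segregation
# ---------------------------------------------------------------------------


def test_family1_wes_segregation_fully_consistent(family1):
    record = datasets.family1_ppip5k2_records()[0]
    report = segregation_report(record, family1, samples=family1.selected(SeqSet.WES))
    assert len(report.consistent) == 10
    assert report.n_scored == 10
    assert report.carrier_without_variant == []
    assert report.penetrance_estimate == 1.0


def test_family1_extended_lists_exactly_the_two_exceptions(family1):
    record = datasets.family1_ppip5k2_records()[0]
    samples = family1.selected(SeqSet.WES) + ["III9", "IV9"]
    report = segregation_report(record, family1, samples=samples)
    assert sorted(report.carrier_without_variant) == ["III9", "IV9"]
    assert len(report.consistent) == 10
    assert report.variant_without_haplotype == []
    assert report.affected_noncarriers_with_variant == []


def test_pcsk1_complete_segregation(family1):
    record = datasets.family1_pcsk1_records()[0]
    report = segregation_report(record, family1, samples=family1.selected(SeqSet.WGS))
    assert report.n_scored == 5
    assert report.carrier_without_variant == []
    assert report.variant_without_haplotype == []
    assert report.affected_noncarriers_with_variant == []


def test_family2_unaffected_carrier_lowers_penetrance(family2):
    record = datasets.family2_ppip5k2_records()[0]
    report = segregation_report(record, family2)
    # 201 is an unaffected linked het: a pure penetrance exception (unscored)
    assert "201" in report.unscored
    assert report.penetrance_estimate == pytest.approx(2 / 3)


def test_segregation_warns_when_nothing_scorable(family1):
    record = datasets.family1_ppip5k2_records()[0]
    empty = VariantRecord(chrom="5", pos=1, ref="A", alt="C", calls={})
    with pytest.warns(UserWarning, match="no scorable"):
        report = segregation_report(empty, family1, samples=[])
    assert report.n_scored == 0 and report.penetrance_estimate is None
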