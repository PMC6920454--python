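"""Gene dropping, cohort simulation, and fixture writing."""

import hashlib

import numpy as np
import pytest
from scipy import stats as sps

from kerafam.filtering import run_cascade
from kerafam.pedigree import (
    Affection,
    Haplotype,
    mendelian_violations,
    parse_ped,
)
from kerafam.simulate import (
    GenomicSimParams,
    SimulationError,
    gene_drop,
    simulate_cohort,
    write_fixture,
)
from kerafam.vcfio import read_vcf


def test_gene_drop_single_founder():
    ped = parse_ped("F A 0 0 1 2")
    assert gene_drop(ped, "A", seed=0) == {"A": True}


def test_gene_drop_requires_a_founder(family1):
    with pytest.raises(SimulationError, match="not a founder"):
        gene_drop(family1, "II5", seed=0)


def test_gene_drop_deterministic_per_seed(family1):
    a = gene_drop(family1, "I1", seed=42)
    b = gene_drop(family1, "I1", seed=42)
    assert a == b
    assert any(gene_drop(family1, "I1", seed=s) != a for s in range(5))


def test_transmission_frequency_is_half():
    """Over 10,000 founder-to-child meioses the child carries the haplotype
    half the time (binomial 95% band), and a chi-square GOF accepts 1:1."""
    ped = parse_ped("F P 0 0 1 2\nF M 0 0 2 1\nF K P M 1 0")
    rng = np.random.default_rng(2019)
    n = 10_000
    hits = sum(gene_drop(ped, "P", seed=rng)["K"] for _ in range(n))
    assert abs(hits / n - 0.5) < 0.02
    chi2 = ((hits - n / 2) ** 2 + ((n - hits) - n / 2) ** 2) / (n / 2)
    assert chi2 < sps.chi2.ppf(0.99, df=1)


def test_gene_drop_haplotypes_are_mendelian(family1):
    """Treating carrier status as a het genotype, 100 independent drops
    produce no Mendelian violations (brute transmission check)."""
    for seed in range(100):
        carries = gene_drop(family1, "I1", seed=seed)
        genotypes = {i: ((0, 1) if c else (0, 0)) for i, c in carries.items()}
        assert mendelian_violations(family1, genotypes) == []


def test_full_penetrance_means_every_affected_is_a_het_carrier(family1):
    cohort = simulate_cohort(
        GenomicSimParams(pedigree=family1, penetrance=1.0, phenocopy_rate=0.0,
                         n_background=0, seed=3)
    )
    causal = cohort.records[0]
    for ind in cohort.pedigree:
        if ind.affected is Affection.AFFECTED:
            assert ind.id in cohort.carriers
            assert causal.calls[ind.id].alleles == (0, 1)


def test_incomplete_penetrance_rate_recovers():
    """At penetrance 0.8 the unaffected fraction among carriers converges
    to 0.2 (binomial band +/-0.03 over many simulated families)."""
    ped = parse_ped(
        "\n".join(
            ["F A 0 0 1 0 ? WES", "F B 0 0 2 0 ? WES"]
            + [f"F K{i} A B 1 0 ? WES" for i in range(8)]
        )
    )
    unaffected = carriers = 0
    for seed in range(300):
        cohort = simulate_cohort(
            GenomicSimParams(pedigree=ped, founder_id="A", penetrance=0.8,
                             n_background=0, min_affected_selected=0, seed=seed)
        )
        for ind in cohort.pedigree:
            if ind.id in cohort.carriers:
                carriers += 1
                if ind.affected is Affection.UNAFFECTED:
                    unaffected += 1
    assert carriers > 500
    assert abs(unaffected / carriers - 0.2) < 0.03


def test_noise_free_genotypes_are_mendelian(family1):
    for seed in range(100):
        cohort = simulate_cohort(
            GenomicSimParams(pedigree=family1, n_background=5,
                             genotype_error_rate=0.0, seed=seed)
        )
        for rec in cohort.records:
            genotypes = {i: c.alleles for i, c in rec.calls.items()}
            assert mendelian_violations(cohort.pedigree, genotypes) == []


def test_genotype_noise_produces_violations(family1):
    noisy = simulate_cohort(
        GenomicSimParams(pedigree=family1, n_background=200,
                         genotype_error_rate=0.2, seed=5)
    )
    n_bad = sum(
        len(mendelian_violations(noisy.pedigree,
                                 {i: c.alleles for i, c in rec.calls.items()}))
        for rec in noisy.records
    )
    assert n_bad > 0


def test_founder_genotypes_match_hardy_weinberg(family1):
    """Aggregate z-tests: founder alt-allele and heterozygote counts match
    their Hardy-Weinberg expectations at the drawn frequencies."""
    cohort = simulate_cohort(
        GenomicSimParams(pedigree=family1, n_background=2000, seed=9)
    )
    founders = [i.id for i in family1.founders]
    mafs, alt_counts, het_counts = [], [], []
    for rec in cohort.records[1:]:
        mafs.append(rec.population_maf)
        alleles = [rec.calls[f].alleles for f in founders]
        alt_counts.append(sum(sum(a) for a in alleles))
        het_counts.append(sum(1 for a in alleles if sum(a) == 1))
    mafs = np.array(mafs)
    n_f = len(founders)
    exp_alt = 2 * n_f * mafs
    z_alt = (np.sum(alt_counts) - exp_alt.sum()) / np.sqrt(
        np.sum(2 * n_f * mafs * (1 - mafs))
    )
    p_het = 2 * mafs * (1 - mafs)
    z_het = (np.sum(het_counts) - np.sum(n_f * p_het)) / np.sqrt(
        np.sum(n_f * p_het * (1 - p_het))
    )
    assert abs(z_alt) < 3 and abs(z_het) < 3


def test_causal_survives_by_construction_and_haplotype_removal_kills_it(family1):
    """With default parameters the spiked variant passes all criteria; at
    reduced penetrance, relabeling one unaffected sequenced carrier as
    haplotype-unlinked turns it into a control-absence casualty."""
    cohort = simulate_cohort(GenomicSimParams(pedigree=family1, seed=2))
    cfg = cohort.filter_config()
    out, _ = run_cascade(cohort.records, cohort.pedigree, cfg)
    assert cohort.causal_key in {r.key for r in out}

    # hunt a low-penetrance replicate with an unaffected sequenced carrier
    for seed in range(50):
        cohort = simulate_cohort(
            GenomicSimParams(pedigree=family1, penetrance=0.7, seed=seed)
        )
        exceptions = [
            ind.id
            for ind in cohort.pedigree
            if ind.id in cohort.carriers
            and ind.affected is Affection.UNAFFECTED
            and ind.sequenced.value in ("wes", "both")
        ]
        if exceptions:
            break
    assert exceptions, "no replicate with an unaffected sequenced carrier"
    out, _ = run_cascade(cohort.records, cohort.pedigree, cohort.filter_config())
    assert cohort.causal_key in {r.key for r in out}
    relabeled = cohort.pedigree.with_statuses(
        haplotype={exceptions[0]: Haplotype.UNLINKED}
    )
    out2, trace2 = run_cascade(cohort.records, relabeled, cohort.filter_config())
    assert cohort.causal_key not in {r.key for r in out2}
    control_step = trace2.steps[1]
    assert control_step.name == "control_absence"
    assert cohort.causal_key in control_step.dropped


def _digest_dir(paths):
    h = hashlib.sha256()
    for key in sorted(paths):
        h.update(paths[key].read_bytes())
    return h.hexdigest()


def test_fixture_round_trip_and_byte_stability(family1, tmp_path):
    cohort = simulate_cohort(
        GenomicSimParams(pedigree=family1, n_background=20, seed=13)
    )
    paths1 = write_fixture(cohort, tmp_path / "a")
    paths2 = write_fixture(
        simulate_cohort(GenomicSimParams(pedigree=family1, n_background=20, seed=13)),
        tmp_path / "b",
    )
    assert _digest_dir(paths1) == _digest_dir(paths2)

    back = read_vcf(paths1["vcf"])
    by_key = {r.key: r for r in back}
    assert set(by_key) == {r.key for r in cohort.records}
    for rec in cohort.records:
        came = by_key[rec.key]
        for sample, call in rec.calls.items():
            assert came.calls[sample].alleles == tuple(sorted(call.alleles))
            assert came.calls[sample].depth == call.depth


def test_empty_record_set_writes_valid_header_only_vcf(tmp_path):
    from kerafam.vcfio import write_vcf

    path = tmp_path / "empty.vcf"
    write_vcf([], ["S1", "S2"], path)
    assert read_vcf(path) == []
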