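"""Variant prioritization rules, allele-frequency arithmetic, Fisher test."""

import itertools
import math
from dataclasses import replace

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import famseg as fs
from famseg.variant_filter import (
    display_frequency,
    normalize_impact,
    read_variant_tsv,
    write_variant_tsv,
)


def make_record(**kwargs):
    base = dict(
        chrom="2", pos=50_847_195, ref="G", alt="A", rsid="rs1",
        impact="MODERATE", sift="deleterious", polyphen="probably_damaging",
        consequence="missense", case_het=28, case_hom=0, case_n=4376,
        control_panels={"thousand_genomes": (29, 8758), "gnomad_nfe": (413, 126558)},
    )
    base.update(kwargs)
    return fs.VariantRecord(**base)


# the two cohort-screen hits: 28 and 10 heterozygous carriers among 4376
# cases, damaging by both annotators, rare in both control panels
P469S = make_record()
H885Y = make_record(
    pos=50_724_817, rsid="rs2", polyphen="possibly_damaging",
    case_het=10,
    control_panels={"thousand_genomes": (11, 8762), "gnomad_nfe": (134, 127740)},
)


# ---------------------------------------------------------------------------
# allele frequency arithmetic
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "het, hom, n, shown",
    [
        (28, 0, 4376, 0.0032),
        (10, 0, 4376, 0.0011),
        (0, 5, 5, 1.0),
        (0, 0, 100, 0.0),
    ],
)
def test_allele_frequency_display(het, hom, n, shown):
    assert display_frequency(fs.allele_frequency(het, hom, n)) == shown


def test_allele_frequency_domain_errors():
    with pytest.raises(ValueError):
        fs.allele_frequency(-1, 0, 10)
    with pytest.raises(ValueError):
        fs.allele_frequency(6, 5, 10)
    with pytest.raises(ValueError):
        fs.allele_frequency(0, 0, 0)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(
    het=st.integers(0, 50), hom=st.integers(0, 50), extra=st.integers(0, 100)
)
def test_allele_frequency_monotone(het, hom, extra):
    n = het + hom + extra + 1
    f = fs.allele_frequency(het, hom, n)
    assert 0.0 <= f <= 1.0
    assert fs.allele_frequency(het + 1, hom, n + 1 + het + hom) <= 1.0
    if het + hom + 1 <= n:
        assert fs.allele_frequency(het + 1, hom, n) > f or het + hom == n


def test_impact_synonyms():
    assert normalize_impact("medium") == "MODERATE"
    assert normalize_impact("Moderate") == "MODERATE"
    assert normalize_impact("HIGH") == "HIGH"
    with pytest.raises(ValueError):
        normalize_impact("severe")


# ---------------------------------------------------------------------------
# family-shared filter
# ---------------------------------------------------------------------------

def test_family_shared_filter_planted_fixture():
    passing = [
        make_record(pos=100 + i, family_carrier_count=6) for i in range(3)
    ]
    decoys = (
        [make_record(pos=200 + i, family_carrier_count=4) for i in range(8)]
        + [make_record(pos=300 + i, family_carrier_count=6, impact="LOW")
           for i in range(5)]
        + [
            make_record(
                pos=400 + i, family_carrier_count=6,
                control_panels={"utah_controls": (30, 1050)},
            )
            for i in range(4)
        ]
    )
    report = fs.family_shared_filter(passing + decoys, shared_in=6)
    assert report.input_count == 20
    assert report.surviving_count == 3
    assert {r.pos for r in report.surviving} == {100, 101, 102}
    assert report.eliminated_by == {
        "shared_in_all_cases": 8,
        "impact": 5,
        "control_frequency": 4,
    }
    assert report.input_count == report.surviving_count + sum(
        report.eliminated_by.values()
    )


def test_family_shared_filter_low_impact_attribution():
    rec = make_record(impact="LOW", family_carrier_count=6)
    report = fs.family_shared_filter([rec])
    assert report.surviving_count == 0
    assert report.eliminated_by == {"impact": 1}


def test_family_shared_filter_empty_input():
    report = fs.family_shared_filter([])
    assert report.input_count == report.surviving_count == 0
    assert report.eliminated_by == {}


def test_missing_annotation_goes_to_unannotated():
    rec = make_record(impact=None, family_carrier_count=6)
    report = fs.family_shared_filter([rec])
    assert report.eliminated_by == {"unannotated": 1}


# ---------------------------------------------------------------------------
# cohort functional filter
# ---------------------------------------------------------------------------

def cohort_fixture():
    decoys = [
        replace(P469S, pos=1, consequence="synonymous"),
        replace(P469S, pos=2, polyphen="benign"),
        replace(P469S, pos=3, sift="tolerated"),
        replace(P469S, pos=4, case_het=3),  # too few carriers
        replace(
            P469S, pos=5,
            control_panels={"thousand_genomes": (200, 8758)},  # too common
        ),
    ]
    return [P469S, H885Y] + decoys


def test_cohort_functional_filter_retains_the_two_hits():
    report = fs.cohort_functional_filter(cohort_fixture())
    assert report.surviving_count == 2
    assert {r.rsid for r in report.surviving} == {"rs1", "rs2"}
    assert report.eliminated_by == {
        "consequence": 1,
        "annotations": 2,
        "carriers": 1,
        "control_frequency": 1,
    }


def test_cohort_filter_control_frequency_rule():
    bad = replace(P469S, control_panels={"panel": (200, 8758)})  # 0.023
    report = fs.cohort_functional_filter([bad])
    assert report.eliminated_by == {"control_frequency": 1}


def test_cohort_filter_possibly_damaging_passes():
    rec = replace(P469S, polyphen="possibly_damaging")
    assert fs.cohort_functional_filter([rec]).surviving_count == 1


def test_filters_are_order_independent_in_surviving_set():
    records = cohort_fixture()
    baseline = {r.variant_id for r in fs.cohort_functional_filter(records).surviving}
    for perm in itertools.islice(itertools.permutations(records), 8):
        got = {r.variant_id for r in fs.cohort_functional_filter(perm).surviving}
        assert got == baseline


# ---------------------------------------------------------------------------
# case-control test
# ---------------------------------------------------------------------------

def fisher_two_sided_oracle(a, an, b, bn):
    """Point-probability two-sided Fisher via hypergeometric enumeration."""
    n11, n1_, n_1 = a, an, a + b
    n = an + bn
    def lp(k):
        return (
            math.lgamma(n_1 + 1) - math.lgamma(k + 1) - math.lgamma(n_1 - k + 1)
            + math.lgamma(n - n_1 + 1) - math.lgamma(n1_ - k + 1)
            - math.lgamma(n - n_1 - n1_ + k + 1)
            + math.lgamma(n1_ + 1) + math.lgamma(n - n1_ + 1) - math.lgamma(n + 1)
        )
    lo, hi = max(0, n_1 + n1_ - n), min(n_1, n1_)
    p_obs = lp(n11)
    total = 0.0
    for k in range(lo, hi + 1):
        if lp(k) <= p_obs + 1e-9:
            total += math.exp(lp(k))
    return min(total, 1.0)


def test_case_control_identical_tables():
    odds, p = fs.case_control_test(5, 100, 5, 100)
    assert odds == pytest.approx(1.0)
    assert p == 1.0


def test_case_control_extreme_difference():
    _, p = fs.case_control_test(100, 200, 0, 200)
    assert p < 1e-6
    assert p == pytest.approx(fisher_two_sided_oracle(100, 200, 0, 200), abs=1e-10)


def test_case_control_haldane_anscombe_on_zero_cell():
    odds, _ = fs.case_control_test(3, 100, 0, 100)
    assert odds == pytest.approx((3.5 * 100.5) / (97.5 * 0.5))


@settings(deadline=None, derandomize=True, max_examples=40)
@given(
    a=st.integers(0, 40), b=st.integers(0, 40),
    an=st.integers(50, 250), bn=st.integers(50, 250),
)
def test_fisher_matches_hypergeometric_oracle(a, b, an, bn):
    _, p = fs.case_control_test(a, an, b, bn)
    assert p == pytest.approx(fisher_two_sided_oracle(a, an, b, bn), abs=1e-10)


def test_case_control_domain_errors():
    with pytest.raises(ValueError):
        fs.case_control_test(10, 5, 1, 100)
    with pytest.raises(ValueError):
        fs.case_control_test(0, 0, 1, 100)


# ---------------------------------------------------------------------------
# TSV round trip
# ---------------------------------------------------------------------------

def test_variant_tsv_round_trip(tmp_path):
    path = tmp_path / "v.tsv"
    write_variant_tsv([P469S, H885Y], path)
    back = read_variant_tsv(path)
    assert [r.variant_id for r in back] == [P469S.variant_id, H885Y.variant_id]
    assert back[0].control_panels == dict(P469S.control_panels)
    assert back[1].polyphen == "possibly_damaging"
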