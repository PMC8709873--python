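"""Segregation probabilities: closed form vs exact peeling vs gene drop."""

import pytest

import famseg as fs
from famseg.segregation import (
    PedigreeTooLargeError,
    single_introduction_probability,
)

from conftest import make_avuncular, make_chain, make_cousins, make_siblings, make_trio


def seg_pair(ped, carriers, q):
    sub = fs.connecting_subgraph(ped, carriers)
    return fs.closed_form_sharing(sub, q), fs.exact_peeling(ped, carriers, q)


# ---------------------------------------------------------------------------
# introduction probability and the leading-order single-introduction term
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "q, expect",
    [(0.0, 0.0), (0.5, 0.75), (0.0032, 0.00638976), (1.0, 1.0)],
)
def test_introduction_probability(q, expect):
    assert fs.introduction_probability(q) == pytest.approx(expect, abs=1e-12)


def test_introduction_probability_domain():
    with pytest.raises(ValueError):
        fs.introduction_probability(-0.1)
    with pytest.raises(ValueError):
        fs.introduction_probability(1.1)


def test_each_meiosis_halves_single_introduction_term():
    q = 1e-6
    for apex in (1, 2):
        for m in range(0, 12):
            ratio = single_introduction_probability(
                q, m, apex
            ) / single_introduction_probability(q, m + 1, apex)
            assert ratio == 2.0


def test_single_introduction_halving_on_chain_pedigrees():
    q = 1e-6
    values = []
    for links in (1, 2, 3, 4):
        ped = make_chain(links)
        sub = fs.connecting_subgraph(ped, ["P0", f"P{links}"])
        assert sub.meioses == links
        values.append(fs.closed_form_sharing(sub, q).p_single_introduction)
    ratios = [values[i] / values[i + 1] for i in range(len(values) - 1)]
    assert ratios == [2.0, 2.0, 2.0]


# ---------------------------------------------------------------------------
# exact peeling
# ---------------------------------------------------------------------------

def test_single_individual_hardy_weinberg():
    ped = fs.Pedigree("ONE", [fs.Individual(id="X", sex="male")])
    r = fs.exact_peeling(ped, ["X"], 0.01)
    assert r.p_any_sharing == pytest.approx(1 - 0.99**2, abs=1e-12)
    assert r.p_conditional == 1.0


def test_sibling_rare_allele_conditional_limits():
    """At q -> 0 a rare allele seen in one sibling is in the other with
    probability 1/2 (index conditioning); conditioning on 'any sibling
    carries' gives 1/3."""
    sibs = make_siblings()
    r = fs.exact_peeling(sibs, ["A", "B"], 1e-6)
    assert r.p_conditional_index == pytest.approx(0.5, abs=1e-4)
    assert r.p_conditional == pytest.approx(1.0 / 3.0, abs=1e-4)


def test_peeling_exactness_bound():
    ped, _ = fs.generate_pedigree(fs.SimConfig(n_generations=7, seed=2))
    carriers = sorted(ped.members)[-8:]
    with pytest.raises(PedigreeTooLargeError, match="genedrop"):
        fs.exact_peeling(ped, carriers, 0.01, max_individuals=10)


def test_parent_child_pair_closed_form_matches_peeling():
    closed, peel = seg_pair(make_trio(), ["F", "C"], 0.001)
    assert closed.p_any_sharing == pytest.approx(peel.p_any_sharing, abs=1e-9)
    assert closed.p_conditional == pytest.approx(peel.p_conditional, abs=1e-9)


@pytest.mark.parametrize("q", [1e-4, 1e-3, 1e-2, 0.1])
@pytest.mark.parametrize(
    "builder, carriers",
    [
        (make_trio, ["F", "C"]),
        (make_siblings, ["A", "B"]),
        (make_cousins, ["C1", "C2"]),
        (make_avuncular, ["U", "N"]),
        (lambda: make_chain(3), ["P0", "P3"]),
    ],
)
def test_closed_form_and_peeling_agree_everywhere(builder, carriers, q):
    closed, peel = seg_pair(builder(), carriers, q)
    assert closed.p_any_sharing == pytest.approx(peel.p_any_sharing, abs=1e-9)
    assert closed.p_conditional == pytest.approx(peel.p_conditional, abs=1e-9)
    assert closed.p_conditional_index == pytest.approx(
        peel.p_conditional_index, abs=1e-9
    )


def test_term_table_sums_to_p_any_and_orders_single_introduction_first():
    sub = fs.connecting_subgraph(make_cousins(), ["C1", "C2"])
    r = fs.closed_form_sharing(sub, 0.001)
    assert sum(v for _, v in r.terms) == pytest.approx(r.p_any_sharing, rel=1e-12)
    # the apex-only configuration dominates for a rare allele
    apex_only = [v for k, v in r.terms if set(k) <= {"GF", "GM"}]
    assert sum(apex_only) > 0.9 * r.p_any_sharing
    assert r.p_single_introduction_exact == pytest.approx(sum(apex_only), rel=1e-12)


def test_probability_ordering_invariants():
    for q in (1e-4, 1e-3, 1e-2, 0.1):
        closed, peel = seg_pair(make_cousins(), ["C1", "C2"], q)
        for r in (closed, peel):
            assert 0 <= r.p_single_introduction <= r.p_any_sharing <= 1
            assert r.p_conditional >= r.p_any_sharing
            assert r.p_conditional_index >= r.p_any_sharing


def test_sharing_increases_with_q():
    values = [
        fs.exact_peeling(make_cousins(), ["C1", "C2"], q).p_any_sharing
        for q in (1e-4, 1e-3, 1e-2, 0.1, 0.5)
    ]
    assert values == sorted(values)
    assert len(set(values)) == len(values)


def test_sharing_decreases_with_relationship_distance():
    """More separating meioses -> smaller sharing probability.

    Strict per-meiosis monotonicity holds for the single-introduction term
    (it halves per meiosis).  For the exact p_any_sharing the sibling pair
    slightly exceeds the parent-child pair at O(q^2) — two possible
    single-origin parents instead of one — so only the leading-order
    separation (cousins far below either pair) is asserted there.
    """
    q = 0.001
    pc = fs.exact_peeling(make_trio(), ["F", "C"], q)
    sib = fs.exact_peeling(make_siblings(), ["A", "B"], q)
    cz = fs.exact_peeling(make_cousins(), ["C1", "C2"], q)
    assert cz.p_any_sharing < sib.p_any_sharing
    assert cz.p_any_sharing < pc.p_any_sharing
    assert (
        cz.p_single_introduction
        < sib.p_single_introduction
        < pc.p_single_introduction
    )


def test_no_marry_in_descent_line_closed_form_matches_peeling():
    """Carriers spanning a founder couple's full descent line (apex plus
    children): no marry-in beyond the apex."""
    sibs = make_siblings()
    closed, peel = seg_pair(sibs, ["F", "M", "A", "B"], 0.01)
    assert closed.p_any_sharing == pytest.approx(peel.p_any_sharing, abs=1e-9)


def test_inbreeding_loop_exact_via_peeling():
    """Half-sib-mating loop: peeling handles it; gene drop confirms."""
    ped = fs.Pedigree(
        "LOOP",
        [
            fs.Individual(id="F", sex="male"),
            fs.Individual(id="M1", sex="female"),
            fs.Individual(id="M2", sex="female"),
            fs.Individual(id="S1", father_id="F", mother_id="M1", sex="male"),
            fs.Individual(id="S2", father_id="F", mother_id="M2", sex="female"),
            fs.Individual(id="C", father_id="S1", mother_id="S2", sex="male"),
        ],
    )
    q = 0.05
    peel = fs.exact_peeling(ped, ["S1", "C"], q)
    est = fs.simulate(ped, ["S1", "C"], q, 400_000, seed=17)
    assert abs(peel.p_any_sharing - est.p_hat) <= 3 * est.se + 1e-12


@pytest.mark.parametrize("q", [1e-3, 1e-2])
def test_triple_oracle_agreement_sibling_pair(q):
    sibs = make_siblings()
    closed, peel = seg_pair(sibs, ["A", "B"], q)
    est = fs.simulate(sibs, ["A", "B"], q, 1_000_000, seed=29)
    assert closed.p_any_sharing == pytest.approx(peel.p_any_sharing, abs=1e-9)
    assert abs(est.p_hat - peel.p_any_sharing) <= 3 * est.se + 1e-12


def test_q_domain_checks():
    sibs = make_siblings()
    with pytest.raises(ValueError):
        fs.exact_peeling(sibs, ["A", "B"], 0.0)
    with pytest.raises(ValueError):
        fs.exact_peeling(sibs, ["A", "B"], 1.0)
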