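"""Shared pedigree fixtures: small families with known genealogy."""

import pytest

from famseg import Individual, Pedigree


def make_trio():
    return Pedigree(
        "TRIO",
        [
            Individual(id="F", sex="male"),
            Individual(id="M", sex="female"),
            Individual(id="C", father_id="F", mother_id="M", sex="male"),
        ],
    )


def make_siblings():
    return Pedigree(
        "SIBS",
        [
            Individual(id="F", sex="male"),
            Individual(id="M", sex="female"),
            Individual(id="A", father_id="F", mother_id="M", sex="male"),
            Individual(id="B", father_id="F", mother_id="M", sex="female"),
        ],
    )


def make_cousins():
    """Grandparental couple, two sons marrying in two spouses, two
    grandchildren who are first cousins (8 members)."""
    return Pedigree(
        "COUSINS",
        [
            Individual(id="GF", sex="male"),
            Individual(id="GM", sex="female"),
            Individual(id="U1", father_id="GF", mother_id="GM", sex="male"),
            Individual(id="U2", father_id="GF", mother_id="GM", sex="male"),
            Individual(id="W1", sex="female"),
            Individual(id="W2", sex="female"),
            Individual(id="C1", father_id="U1", mother_id="W1", sex="male"),
            Individual(id="C2", father_id="U2", mother_id="W2", sex="female"),
        ],
    )


def make_chain(n_links: int) -> Pedigree:
    """Direct descent chain: founder couple, then n_links generations of a
    single child mated to a marry-in spouse."""
    members = [
        Individual(id="P0", sex="male"),
        Individual(id="S0", sex="female"),
    ]
    for i in range(1, n_links + 1):
        father, mother = f"P{i-1}", f"S{i-1}"
        members.append(
            Individual(id=f"P{i}", father_id=father, mother_id=mother, sex="male")
        )
        if i < n_links:
            members.append(Individual(id=f"S{i}", sex="female"))
    return Pedigree("CHAIN", members)


def make_avuncular():
    """Uncle and nephew: 3 meioses."""
    return Pedigree(
        "AVUNC",
        [
            Individual(id="GF", sex="male"),
            Individual(id="GM", sex="female"),
            Individual(id="U", father_id="GF", mother_id="GM", sex="male"),
            Individual(id="P", father_id="GF", mother_id="GM", sex="female"),
            Individual(id="H", sex="male"),
            Individual(id="N", father_id="H", mother_id="P", sex="male"),
        ],
    )


@pytest.fixture
def trio():
    return make_trio()


@pytest.fixture
def siblings():
    return make_siblings()


@pytest.fixture
def cousins():
    return make_cousins()


@pytest.fixture
def avuncular():
    return make_avuncular()
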