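"""Probability that distant affected relatives share a rare variant by chance.

The null model: every pedigree founder draws a diploid genotype from
Hardy-Weinberg equilibrium at population allele frequency ``q`` and alleles
descend by fair Mendelian transmission.  The question answered here is how
surprising it is that all genotyped carrier cases in an extended family
carry the same rare allele — decomposed into a single introduction at the
family's apex transmitted across the separating meioses, versus independent
introductions through marry-in spouses.

Two exact routes are implemented and must agree:

* :func:`closed_form_sharing` — structured summation over the connecting
  subgraph: the apex couple's genotypes and the marry-in co-parent at each
  meiosis are integrated against Hardy-Weinberg priors down the descent
  tree, with a per-introduction-configuration term table.
* :func:`exact_peeling` — generic sum-product variable elimination over the
  full ancestral closure of the carriers (also valid with inbreeding loops).

The headline ``p_single_introduction`` follows the verbal decomposition
``[1 - (1-q)^(2c)] * (1/2)^M`` (``c`` = individuals at the introduction
point, ``M`` = meioses): the chance the apex carries the allele at all,
times fair transmission across every separating meiosis.  It is the
small-``q`` leading order of the exact single-origin probability (also
reported) and halves exactly per additional meiosis.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

from .pedigree import ConnectingSubgraph, Pedigree, connecting_subgraph

#: exactness bound for peeling (individuals in the pruned pedigree)
PEELING_MAX_INDIVIDUALS = 25

#: smallest allele frequency with comfortable double-precision headroom in
#: the linear-space products used below
MIN_Q = 1e-8

_ONES = np.ones(3)


class PedigreeTooLargeError(Exception):
    """Pruned pedigree exceeds the exactness bound; use genedrop.simulate."""

    def __init__(self, size: int, bound: int = PEELING_MAX_INDIVIDUALS):
        self.size = size
        self.bound = bound
        super().__init__(
            f"pruned pedigree has {size} members (> {bound}); "
            "use genedrop.simulate for a Monte Carlo estimate"
        )


def _check_q(q: float, open_interval: bool = False) -> None:
    if open_interval:
        if not MIN_Q <= q < 1.0:
            raise ValueError(f"allele frequency {q} outside [{MIN_Q}, 1)")
    elif not 0.0 <= q <= 1.0:
        raise ValueError(f"allele frequency {q} outside [0, 1]")


def introduction_probability(q: float) -> float:
    """Hardy-Weinberg probability that a diploid founder carries >= 1 copy."""
    _check_q(q)
    return 1.0 - (1.0 - q) ** 2


def hardy_weinberg(q: float) -> np.ndarray:
    """Genotype prior [P(0 copies), P(1), P(2)] at allele frequency ``q``."""
    return np.array([(1.0 - q) ** 2, 2.0 * q * (1.0 - q), q * q])


def _mendel_cpt() -> np.ndarray:
    """T[gf, gm, gc] = P(child copies gc | father gf, mother gm)."""
    t = np.zeros((3, 3, 3))
    for gf in range(3):
        for gm in range(3):
            tf, tm = gf / 2.0, gm / 2.0
            t[gf, gm, 0] = (1 - tf) * (1 - tm)
            t[gf, gm, 1] = tf * (1 - tm) + (1 - tf) * tm
            t[gf, gm, 2] = tf * tm
    return t


_MENDEL = _mendel_cpt()
_CARRY = np.array([0.0, 1.0, 1.0])
_NO_CARRY = np.array([1.0, 0.0, 0.0])


def single_introduction_probability(
    q: float, meioses: int, apex_size: int = 1
) -> float:
    """Leading-order single-introduction term ``[1-(1-q)^(2c)] * (1/2)^M``."""
    _check_q(q)
    if meioses < 0:
        raise ValueError("meioses must be >= 0")
    if apex_size not in (1, 2):
        raise ValueError("apex_size must be 1 (individual) or 2 (couple)")
    return (1.0 - (1.0 - q) ** (2 * apex_size)) * 0.5**meioses


@dataclass(frozen=True)
class SegregationResult:
    """Sharing probabilities for one (variant, family) carrier configuration.

    ``p_any_sharing`` is the unconditional null probability that every
    carrier holds >= 1 copy; ``p_conditional`` conditions on at least one
    carrier holding a copy (exactly 1 for a single carrier);
    ``p_conditional_index`` conditions instead on a designated index
    carrier holding a copy — the convention under which a rare allele in
    one sibling is found in the other with probability 1/2.  Since any
    non-inbred member is marginally Hardy-Weinberg under gene dropping,
    ``p_conditional_index = p_any_sharing / (1 - (1-q)^2)``.  ``terms``
    (closed form only) decomposes ``p_any_sharing`` exactly by introduction
    configuration: each entry maps the set of founders carrying the allele
    (apex member ids and marry-in ids) to the probability that exactly those
    sources carry it and every carrier received a copy.
    """

    variant_id: str
    family_id: str
    q: float
    meioses: int
    p_single_introduction: float
    p_any_sharing: float
    p_conditional: float
    p_conditional_index: float
    method: str
    apex_size: int = 1
    n_carriers: int = 0
    p_single_introduction_exact: float | None = None
    terms: tuple[tuple[tuple[str, ...], float], ...] = ()
    notes: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        d = {
            "variant_id": self.variant_id,
            "family_id": self.family_id,
            "q": self.q,
            "meioses": self.meioses,
            "p_single_introduction": self.p_single_introduction,
            "p_any_sharing": self.p_any_sharing,
            "p_conditional": self.p_conditional,
            "p_conditional_index": self.p_conditional_index,
            "method": self.method,
            "apex_size": self.apex_size,
            "n_carriers": self.n_carriers,
        }
        if self.p_single_introduction_exact is not None:
            d["p_single_introduction_exact"] = self.p_single_introduction_exact
        if self.terms:
            d["terms"] = [
                {"introducers": list(k), "probability": v} for k, v in self.terms
            ]
        if self.notes:
            d["notes"] = list(self.notes)
        return d


# ---------------------------------------------------------------------------
# Exact peeling: sum-product variable elimination over genotype variables
# ---------------------------------------------------------------------------

class _Factor:
    """Probability table over named genotype variables (domain {0,1,2})."""

    __slots__ = ("vars", "table")

    def __init__(self, variables: tuple[str, ...], table: np.ndarray):
        self.vars = variables
        self.table = table

    def multiply(self, other: "_Factor") -> "_Factor":
        merged = self.vars + tuple(v for v in other.vars if v not in self.vars)
        a = self.table.reshape(
            self.table.shape + (1,) * (len(merged) - len(self.vars))
        )
        positions = [merged.index(v) for v in other.vars]
        b = np.transpose(other.table, np.argsort(positions))
        shape = [3 if i in positions else 1 for i in range(len(merged))]
        return _Factor(merged, a * b.reshape(shape))

    def sum_out(self, var: str) -> "_Factor":
        axis = self.vars.index(var)
        return _Factor(
            tuple(v for v in self.vars if v != var), self.table.sum(axis=axis)
        )


def _evidence_probability(
    ped: Pedigree, q: float, evidence: Mapping[str, np.ndarray]
) -> float:
    """P(evidence) by variable elimination, deepest individuals first."""
    prior = hardy_weinberg(q)
    factors: list[_Factor] = []
    for ind in ped:
        if ind.is_founder:
            factors.append(_Factor((ind.id,), prior.copy()))
        else:
            factors.append(
                _Factor((ind.father_id, ind.mother_id, ind.id), _MENDEL.copy())
            )
        if ind.id in evidence:
            factors.append(_Factor((ind.id,), np.asarray(evidence[ind.id], float)))
    for var in reversed(list(nx.lexicographical_topological_sort(ped.graph))):
        involved = [f for f in factors if var in f.vars]
        factors = [f for f in factors if var not in f.vars]
        if not involved:
            continue
        prod = involved[0]
        for f in involved[1:]:
            prod = prod.multiply(f)
        factors.append(prod.sum_out(var))
    result = 1.0
    for f in factors:  # every variable eliminated: scalars remain
        result *= float(f.table)
    return result


def exact_peeling(
    ped: Pedigree,
    carriers: Iterable[str],
    q: float,
    variant_id: str = "",
    max_individuals: int = PEELING_MAX_INDIVIDUALS,
) -> SegregationResult:
    """Exact sharing probabilities by summation over founder genotypes.

    The pedigree is pruned to the ancestral closure of the carriers before
    elimination; founders draw Hardy-Weinberg(q) genotypes and non-founders
    follow the Mendelian transmission table.  Raises
    :class:`PedigreeTooLargeError` beyond ``max_individuals`` pruned members.
    """
    carriers = sorted(set(carriers))
    if not carriers:
        raise ValueError("carrier set is empty")
    _check_q(q, open_interval=True)
    pruned = ped.subpedigree(carriers)
    if len(pruned) > max_individuals:
        raise PedigreeTooLargeError(len(pruned), max_individuals)

    p_any = _evidence_probability(pruned, q, {c: _CARRY for c in carriers})
    p_none = _evidence_probability(pruned, q, {c: _NO_CARRY for c in carriers})
    p_cond = 1.0 if len(carriers) == 1 else p_any / (1.0 - p_none)
    p_cond_index = 1.0 if len(carriers) == 1 else p_any / introduction_probability(q)

    sub = connecting_subgraph(ped, carriers)
    return SegregationResult(
        variant_id=variant_id,
        family_id=ped.family_id,
        q=q,
        meioses=sub.meioses,
        p_single_introduction=single_introduction_probability(
            q, sub.meioses, sub.apex_size
        ),
        p_any_sharing=p_any,
        p_conditional=p_cond,
        p_conditional_index=p_cond_index,
        method="exact_peeling",
        apex_size=sub.apex_size,
        n_carriers=len(carriers),
    )


# ---------------------------------------------------------------------------
# Closed form on the connecting subgraph
# ---------------------------------------------------------------------------

def _descent_tree(sub: ConnectingSubgraph) -> dict[str, list[str]]:
    kids: dict[str, list[str]] = {}
    for u, v in sub.tree_edges:
        kids.setdefault(u, []).append(v)
    for v in kids.values():
        v.sort()
    return kids


class _SubgraphModel:
    """Descent tree of a connecting subgraph with pluggable co-parent priors.

    Children of the apex couple draw from both apex genotypes; every other
    transmitted-to child has one tree parent and one external co-parent whose
    genotype is either integrated against Hardy-Weinberg(q), pinned to a
    fixed value, or pinned to zero, depending on the quantity wanted.
    """

    def __init__(self, sub: ConnectingSubgraph, q: float):
        self.sub = sub
        self.q = q
        self.prior = hardy_weinberg(q)
        self.kids = _descent_tree(sub)
        self.apex = sorted(sub.founder_introducers)
        roots = [a for a in self.apex if a in self.kids]
        self.root = roots[0] if roots else self.apex[0]
        self.partner = next((a for a in self.apex if a != self.root), None)
        tree_members = {u for u, _ in sub.tree_edges} | {
            v for _, v in sub.tree_edges
        }
        for co in sub.co_parents.values():
            if co in tree_members:
                raise ValueError(
                    f"co-parent {co!r} lies on the descent tree (inbreeding "
                    "loop); use exact_peeling"
                )
        self.marry_ins = sorted(set(sub.co_parents.values()))
        # marginal transmission matrices A[g_tree_parent, g_child]
        self._marginal = np.tensordot(self.prior, _MENDEL, axes=([0], [1]))

    def child_matrix(
        self, child: str, co_genotypes: Mapping[str, int] | None
    ) -> np.ndarray:
        co = self.sub.co_parents.get(child)
        if co is None:  # direct child of the apex couple, handled by caller
            raise KeyError(child)
        if co_genotypes is None:
            return self._marginal
        return _MENDEL[:, co_genotypes[co], :]

    def conditional(
        self,
        g_root: int,
        g_partner: int | None,
        indicator: np.ndarray,
        co_genotypes: Mapping[str, int] | None,
    ) -> float:
        """P(all carrier constraints met | apex genotypes, co-parents)."""
        carriers = self.sub.carriers
        kids = self.kids

        def msg(node: str) -> np.ndarray:
            f = indicator if node in carriers else _ONES
            out = np.array(f, float)
            for child in kids.get(node, ()):
                out = out * (self.child_matrix(child, co_genotypes) @ msg(child))
            return out

        val = 1.0
        for child in kids.get(self.root, ()):
            m = msg(child)
            if child in self.sub.co_parents:
                val *= float(self.child_matrix(child, co_genotypes)[g_root] @ m)
            else:
                assert g_partner is not None
                val *= float(_MENDEL[g_root, g_partner] @ m)
        return val

    def apex_sum(
        self,
        indicator: np.ndarray,
        co_genotypes: Mapping[str, int] | None = None,
        apex_filter=None,
    ) -> float:
        """Sum over apex genotypes of prior * carrier-indicator * conditional."""
        carriers = self.sub.carriers
        total = 0.0
        g_partner_range = range(3) if self.partner is not None else (None,)
        for g_root in range(3):
            if self.root in carriers and indicator[g_root] == 0.0:
                continue
            for g_partner in g_partner_range:
                if (
                    self.partner is not None
                    and self.partner in carriers
                    and indicator[g_partner] == 0.0
                ):
                    continue
                if apex_filter is not None and not apex_filter(g_root, g_partner):
                    continue
                w = self.prior[g_root]
                if g_partner is not None:
                    w *= self.prior[g_partner]
                total += w * self.conditional(
                    g_root, g_partner, indicator, co_genotypes
                )
        return total


def closed_form_sharing(
    sub: ConnectingSubgraph,
    q: float,
    variant_id: str = "",
    term_table_max_sources: int = 8,
) -> SegregationResult:
    """Sharing probabilities computed on the connecting subgraph alone.

    Sums over the genotypes of the apex (individual, or couple contributing
    the ``1-(1-q)^4`` carrier mass) and of the marry-in co-parent at each
    meiosis, each drawn from Hardy-Weinberg(q), with Mendelian transmission
    down the descent tree.  Exact whenever the subgraph is loop-free and
    every co-parent is a pedigree founder — the extended-family situation
    the model targets; a co-parent with in-pedigree ancestry is treated as a
    population draw (use :func:`exact_peeling` for exactness then).
    """
    _check_q(q, open_interval=True)
    model = _SubgraphModel(sub, q)

    p_any = float(model.apex_sum(_CARRY))
    # joint probability: apex carries, no marry-in does, all carriers carry
    p_single_exact = float(
        model.apex_sum(
            _CARRY,
            co_genotypes={m: 0 for m in model.marry_ins},
            apex_filter=lambda ga, gb: ga > 0 or (gb is not None and gb > 0),
        )
        * model.prior[0] ** len(model.marry_ins)
    )
    if len(sub.carriers) == 1:
        p_cond = 1.0
        p_cond_index = 1.0
    else:
        p_none = float(model.apex_sum(_NO_CARRY))
        p_cond = p_any / (1.0 - p_none)
        p_cond_index = p_any / introduction_probability(q)

    notes: list[str] = []
    terms = _term_table(model, term_table_max_sources)
    if not terms and (len(model.apex) + len(model.marry_ins)) > term_table_max_sources:
        notes.append(
            f"term table omitted: more than {term_table_max_sources} "
            "introduction sources"
        )
    return SegregationResult(
        variant_id=variant_id,
        family_id=sub.family_id,
        q=q,
        meioses=sub.meioses,
        p_single_introduction=single_introduction_probability(
            q, sub.meioses, sub.apex_size
        ),
        p_any_sharing=p_any,
        p_conditional=p_cond,
        p_conditional_index=p_cond_index,
        method="closed_form",
        apex_size=sub.apex_size,
        n_carriers=len(sub.carriers),
        p_single_introduction_exact=p_single_exact,
        terms=terms,
        notes=tuple(notes),
    )


def _term_table(
    model: _SubgraphModel, max_sources: int
) -> tuple[tuple[tuple[str, ...], float], ...]:
    """Exact decomposition of p_any_sharing by the set of carrying founders."""
    sources = model.apex + model.marry_ins
    if len(sources) > max_sources:
        return ()
    prior = model.prior
    table: dict[tuple[str, ...], float] = {}
    for combo in itertools.product(range(3), repeat=len(model.marry_ins)):
        co_genos = dict(zip(model.marry_ins, combo))
        w_marry = float(np.prod([prior[g] for g in combo])) if combo else 1.0
        if w_marry == 0.0:
            continue
        carrying_marry = tuple(m for m, g in co_genos.items() if g > 0)
        for g_root in range(3):
            if model.root in model.sub.carriers and _CARRY[g_root] == 0.0:
                continue
            for g_partner in range(3) if model.partner is not None else (None,):
                if (
                    model.partner is not None
                    and model.partner in model.sub.carriers
                    and _CARRY[g_partner] == 0.0
                ):
                    continue
                w = w_marry * prior[g_root]
                if g_partner is not None:
                    w *= prior[g_partner]
                p = w * model.conditional(g_root, g_partner, _CARRY, co_genos)
                if p == 0.0:
                    continue
                key_apex: tuple[str, ...] = ()
                if g_root > 0:
                    key_apex += (model.root,)
                if g_partner is not None and g_partner > 0:
                    key_apex += (model.partner,)
                key = tuple(sorted(key_apex)) + carrying_marry
                table[key] = table.get(key, 0.0) + float(p)
    return tuple(sorted(table.items()))
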