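"""Pedigree ingestion, validation and genealogical queries.

A pedigree is a directed acyclic graph of individuals with parent->child
edges derived from PED-style parentage columns.  The queries this module
provides are the genealogical primitives of the familial rare-variant
analysis: founder identification, the minimal ancestral subgraph connecting
a set of variant carriers (whose transmission-edge count is the "meioses"
separating the carriers), and the classical kinship coefficient.

Meioses convention
------------------
One meiosis is one parent->child transmission event.  In the connecting
subgraph a mated couple acts as a single transmitting node, so two full
siblings are separated by 2 meioses (apex couple -> sib, apex couple -> sib)
and first cousins by 4, matching genealogical usage.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx

MISSING = "0"

SEX_CODES = {"1": "male", "2": "female", "0": "unknown"}
SEX_TO_CODE = {v: k for k, v in SEX_CODES.items()}
PHENO_CODES = {"2": "affected", "1": "unaffected", "0": "unknown", "-9": "unknown"}
PHENO_TO_CODE = {"affected": "2", "unaffected": "1", "unknown": "0"}


class PedigreeError(Exception):
    """Base class for pedigree problems."""


class PedParseError(PedigreeError):
    """Malformed PED line; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


class PedigreeValidationError(PedigreeError):
    """Structural validation failure; lists the offending individual ids."""

    def __init__(self, message: str, offenders: Iterable[str] = ()):
        self.offenders = sorted(set(offenders))
        if self.offenders:
            message = f"{message}: {', '.join(self.offenders)}"
        super().__init__(message)


class DisconnectedCarriersError(PedigreeError):
    """Carriers share no common ancestor; carries the connectivity partition."""

    def __init__(self, partition: Sequence[frozenset[str]]):
        self.partition = [frozenset(g) for g in partition]
        groups = "; ".join("{" + ", ".join(sorted(g)) + "}" for g in self.partition)
        super().__init__(f"carriers have no common ancestor; components: {groups}")


@dataclass(frozen=True)
class Individual:
    """One pedigree member.

    ``affected`` means the ascertained phenotype — in the motivating study,
    suicide death.  ``father_id``/``mother_id`` are ``None`` for founders;
    parentage is all-or-nothing (a half-specified parent pair is rejected).
    """

    id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: str = "unknown"
    affected: str = "unknown"
    genotyped: bool = False
    birth_year: int | None = None
    stratum: str | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female", "unknown"):
            raise ValueError(f"bad sex {self.sex!r} for {self.id}")
        if self.affected not in ("affected", "unaffected", "unknown"):
            raise ValueError(f"bad affection {self.affected!r} for {self.id}")

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


class Pedigree:
    """Validated family graph with parent->child edges.

    Parameters
    ----------
    family_id : str
    members : iterable of Individual

    Raises
    ------
    PedigreeValidationError
        On half-specified parentage, dangling parent references, ancestry
        cycles, sex-inconsistent parent roles, non-founders of unknown sex,
        or an empty founder set.
    """

    def __init__(self, family_id: str, members: Iterable[Individual]):
        self.family_id = family_id
        self._members: dict[str, Individual] = {}
        for ind in members:
            if ind.id in self._members:
                raise PedigreeValidationError("duplicate individual id", [ind.id])
            self._members[ind.id] = ind
        self.graph = nx.DiGraph()
        self.graph.add_nodes_from(self._members)
        for ind in self._members.values():
            for parent in (ind.father_id, ind.mother_id):
                if parent is not None:
                    self.graph.add_edge(parent, ind.id)
        self._validate()
        self._depth = self._generation_depths()

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._members)

    def __iter__(self) -> Iterator[Individual]:
        return iter(self._members.values())

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._members

    def __getitem__(self, individual_id: str) -> Individual:
        try:
            return self._members[individual_id]
        except KeyError:
            raise KeyError(
                f"unknown individual {individual_id!r} in family {self.family_id}"
            ) from None

    @property
    def members(self) -> Mapping[str, Individual]:
        return dict(self._members)

    # -- validation ---------------------------------------------------------
    def _validate(self) -> None:
        half = [
            i.id
            for i in self
            if (i.father_id is None) != (i.mother_id is None)
        ]
        if half:
            raise PedigreeValidationError("half-specified parentage", half)
        dangling = [
            parent
            for i in self
            for parent in (i.father_id, i.mother_id)
            if parent is not None and parent not in self._members
        ]
        if dangling:
            raise PedigreeValidationError("parent not a pedigree member", dangling)
        for i in self:
            if i.father_id is not None and self[i.father_id].sex == "female":
                raise PedigreeValidationError("father is female", [i.father_id])
            if i.mother_id is not None and self[i.mother_id].sex == "male":
                raise PedigreeValidationError("mother is male", [i.mother_id])
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise PedigreeValidationError(
                "ancestry cycle", {u for u, _ in cycle}
            )
        bad_sex = [i.id for i in self if i.sex == "unknown" and not i.is_founder]
        if bad_sex:
            raise PedigreeValidationError(
                "unknown sex permitted for founders only", bad_sex
            )
        if not self.founders():
            raise PedigreeValidationError("pedigree has no founders")

    def _generation_depths(self) -> dict[str, int]:
        depth: dict[str, int] = {}
        for node in nx.topological_sort(self.graph):
            preds = list(self.graph.predecessors(node))
            depth[node] = 0 if not preds else 1 + max(depth[p] for p in preds)
        return depth

    # -- queries ------------------------------------------------------------
    def founders(self) -> set[str]:
        """Ids of members with both parents missing."""
        return {i.id for i in self if i.is_founder}

    def parents(self, individual_id: str) -> tuple[str, str] | None:
        ind = self[individual_id]
        if ind.is_founder:
            return None
        return ind.father_id, ind.mother_id  # type: ignore[return-value]

    def children(self, individual_id: str) -> set[str]:
        return set(self.graph.successors(individual_id))

    def ancestors(self, individual_id: str, include_self: bool = True) -> set[str]:
        anc = nx.ancestors(self.graph, individual_id)
        if include_self:
            anc = anc | {individual_id}
        return anc

    def descendants(self, individual_id: str, include_self: bool = False) -> set[str]:
        des = nx.descendants(self.graph, individual_id)
        if include_self:
            des = des | {individual_id}
        return des

    def depth(self, individual_id: str) -> int:
        return self._depth[individual_id]

    def ancestral_closure(self, ids: Iterable[str]) -> set[str]:
        """All ancestors of ``ids`` plus the co-parents needed to close the
        set under 'every non-founder keeps both parents'."""
        closure: set[str] = set()
        stack = list(ids)
        while stack:
            node = stack.pop()
            if node in closure:
                continue
            closure.add(node)
            pair = self.parents(node)
            if pair:
                stack.extend(pair)
        return closure

    def subpedigree(self, ids: Iterable[str]) -> "Pedigree":
        """Pedigree induced on the ancestral closure of ``ids``."""
        keep = self.ancestral_closure(ids)
        return Pedigree(self.family_id, [self._members[i] for i in keep])

    # -- kinship ------------------------------------------------------------
    def kinship_coefficient(self, a: str, b: str) -> float:
        """Recursive kinship coefficient phi(a, b).

        phi(a, a) = (1 + F_a)/2 with F_a the inbreeding coefficient
        (phi of a's parents), so 0.5 for a non-inbred individual.
        """
        self[a], self[b]  # noqa: B018 - raise on unknown ids
        return self._kinship(a, b, {})

    def _kinship(self, a: str, b: str, memo: dict) -> float:
        if a > b:
            a, b = b, a
        key = (a, b)
        if key in memo:
            return memo[key]
        if a == b:
            pair = self.parents(a)
            val = 0.5 * (1.0 + (self._kinship(*pair, memo) if pair else 0.0))
        else:
            # recurse through the parents of the deeper individual, which is
            # guaranteed not to be an ancestor of the other
            x, y = (a, b) if self._depth[a] >= self._depth[b] else (b, a)
            pair = self.parents(x)
            if pair is None:
                pair = self.parents(y)
                if pair is None:
                    val = 0.0  # two distinct founders: unrelated by convention
                else:
                    val = 0.5 * (
                        self._kinship(pair[0], x, memo)
                        + self._kinship(pair[1], x, memo)
                    )
            else:
                val = 0.5 * (
                    self._kinship(pair[0], y, memo) + self._kinship(pair[1], y, memo)
                )
        memo[key] = val
        return val

    # -- export -------------------------------------------------------------
    def to_dot(self) -> str:
        """Tiny GraphViz export (marriage nodes omitted; edges parent->child)."""
        lines = [f'digraph "{self.family_id}" {{']
        for ind in self:
            shape = {"male": "box", "female": "ellipse"}.get(ind.sex, "diamond")
            fill = ', style=filled, fillcolor="grey"' if ind.affected == "affected" else ""
            lines.append(f'  "{ind.id}" [shape={shape}{fill}];')
        for u, v in self.graph.edges:
            lines.append(f'  "{u}" -> "{v}";')
        lines.append("}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# PED input / output
# ---------------------------------------------------------------------------

def _parse_extra(token: str, name: str):
    if name == "genotyped":
        return token not in ("0", "", "NA")
    if name == "birth_year":
        return None if token in ("0", "", "NA") else int(token)
    return None if token in ("", "NA") else token


def read_ped(path: str | Path, sidecar: str | Path | None = None) -> list[Pedigree]:
    """Read a whitespace-delimited 6+ column PED file.

    Columns: family, id, father, mother, sex (1=male, 2=female, 0=unknown),
    phenotype (2=affected, 1=unaffected, 0/-9=unknown).  ``"0"`` marks a
    missing parent.  A JSON sidecar ``{"7": "genotyped", "8": "birth_year",
    "9": "stratum"}`` maps 1-based extra column numbers to attribute names;
    by default ``<path>.json`` is used when it exists.

    Returns one validated :class:`Pedigree` per family id, in file order.
    """
    path = Path(path)
    extra_map: dict[int, str] = {}
    if sidecar is None:
        candidate = path.with_suffix(path.suffix + ".json")
        sidecar = candidate if candidate.exists() else None
    if sidecar is not None:
        extra_map = {
            int(k): v for k, v in json.loads(Path(sidecar).read_text()).items()
        }

    families: dict[str, list[Individual]] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        if len(tokens) < 6:
            raise PedParseError(
                f"expected >= 6 whitespace-delimited columns, got {len(tokens)}",
                lineno,
            )
        fam, iid, fid, mid, sex, pheno = tokens[:6]
        if sex not in SEX_CODES:
            raise PedParseError(f"bad sex code {sex!r}", lineno)
        if pheno not in PHENO_CODES:
            raise PedParseError(f"bad phenotype code {pheno!r}", lineno)
        attrs: dict = {}
        for col, name in extra_map.items():
            if col - 1 < len(tokens):
                try:
                    attrs[name] = _parse_extra(tokens[col - 1], name)
                except ValueError:
                    raise PedParseError(
                        f"bad value {tokens[col - 1]!r} for column {name}", lineno
                    ) from None
        families.setdefault(fam, []).append(
            Individual(
                id=iid,
                father_id=None if fid == MISSING else fid,
                mother_id=None if mid == MISSING else mid,
                sex=SEX_CODES[sex],
                affected=PHENO_CODES[pheno],
                **attrs,
            )
        )
    if not families:
        raise PedParseError("empty PED file", 0)
    return [Pedigree(fam, members) for fam, members in families.items()]


def read_single_ped(path: str | Path, sidecar: str | Path | None = None) -> Pedigree:
    """Read a PED file expected to contain exactly one family."""
    peds = read_ped(path, sidecar)
    if len(peds) != 1:
        raise PedigreeError(f"expected one family, found {len(peds)}")
    return peds[0]


def write_ped(
    pedigrees: Pedigree | Iterable[Pedigree],
    path: str | Path,
    sidecar: str | Path | None = None,
    extra_columns: Sequence[str] = (),
) -> None:
    """Write pedigrees as tab-delimited PED; inverse of :func:`read_ped`.

    ``extra_columns`` appends attribute columns (genotyped/birth_year/stratum)
    and records their mapping in a JSON sidecar so the round trip preserves them.
    """
    if isinstance(pedigrees, Pedigree):
        pedigrees = [pedigrees]
    lines = []
    for ped in pedigrees:
        for ind in ped:
            row = [
                ped.family_id,
                ind.id,
                ind.father_id or MISSING,
                ind.mother_id or MISSING,
                SEX_TO_CODE[ind.sex],
                PHENO_TO_CODE[ind.affected],
            ]
            for name in extra_columns:
                value = getattr(ind, name)
                if name == "genotyped":
                    row.append("1" if value else "0")
                else:
                    row.append(MISSING if value is None else str(value))
            lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")
    if extra_columns:
        mapping = {str(7 + i): name for i, name in enumerate(extra_columns)}
        if sidecar is None:
            sidecar = Path(path).with_suffix(Path(path).suffix + ".json")
        Path(sidecar).write_text(json.dumps(mapping, sort_keys=True))


# ---------------------------------------------------------------------------
# Connecting subgraph / meioses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConnectingSubgraph:
    """Minimal ancestral subgraph linking a carrier set.

    ``meioses`` counts parent->child transmission events in the descent tree
    rooted at the apex (a couple at the apex transmits as one node).
    ``founder_introducers`` is the apex: the single candidate introduction
    point of the shared allele (one id, or both spouses of the apex couple).
    ``marry_in`` are pedigree founders inside the subgraph other than the
    apex — each an independent potential source of the allele from the
    population.  ``co_parents`` maps each transmitted-to child to its parent
    outside the descent tree (empty string when the co-parent is the apex
    spouse already counted in the apex).
    """

    family_id: str
    carriers: frozenset[str]
    nodes: frozenset[str]
    tree_edges: tuple[tuple[str, str], ...]
    meioses: int
    founder_introducers: frozenset[str]
    marry_in: frozenset[str]
    co_parents: Mapping[str, str] = field(default_factory=dict)
    tied_apexes: tuple[str, ...] = ()

    @property
    def apex_size(self) -> int:
        """Number of individuals at the introduction point (1 or 2)."""
        return len(self.founder_introducers)


def _directed_paths(ped: Pedigree, src: str, dst: str) -> list[list[str]]:
    if src == dst:
        return [[src]]
    return [list(p) for p in nx.all_simple_paths(ped.graph, src, dst)]


def _min_union_edges(
    ped: Pedigree, apex: str, carriers: Sequence[str], cap: int = 200_000
) -> tuple[set[tuple[str, str]], int] | None:
    """Smallest union of directed apex->carrier paths, exact by enumeration.

    Inbreeding loops give several paths per carrier; carrier sets are small
    (<= ~10) so exhaustive choice over path combinations is affordable.
    """
    per_carrier = []
    for c in carriers:
        paths = _directed_paths(ped, apex, c)
        if not paths:
            return None
        per_carrier.append(paths)
    n_combos = 1
    for paths in per_carrier:
        n_combos *= len(paths)
    best: set[tuple[str, str]] | None = None
    if n_combos <= cap:
        for combo in itertools.product(*per_carrier):
            edges = {
                (p[i], p[i + 1]) for p in combo for i in range(len(p) - 1)
            }
            if best is None or len(edges) < len(best):
                best = edges
    else:  # fall back to greedy union of shortest paths
        best = set()
        for paths in per_carrier:
            path = min(paths, key=len)
            best |= {(path[i], path[i + 1]) for i in range(len(path) - 1)}
    assert best is not None
    return best, len(best)


def _carrier_partition(ped: Pedigree, carriers: Sequence[str]) -> list[frozenset[str]]:
    anc = {c: ped.ancestors(c) for c in carriers}
    g = nx.Graph()
    g.add_nodes_from(carriers)
    for a, b in itertools.combinations(carriers, 2):
        if anc[a] & anc[b]:
            g.add_edge(a, b)
    return [frozenset(comp) for comp in nx.connected_components(g)]


def connecting_subgraph(ped: Pedigree, carriers: Iterable[str]) -> ConnectingSubgraph:
    """Minimal ancestral subgraph connecting ``carriers``; see module docstring.

    The apex (common-ancestor individual, promoted to the mated couple when
    both spouses are equally minimal common ancestors) is chosen to minimise
    the total meioses; remaining ties break to the lexicographically smallest
    apex id and all tied apexes are reported.
    """
    carriers = sorted(set(carriers))
    if not carriers:
        raise ValueError("carrier set is empty")
    for c in carriers:
        ped[c]
    # candidate apexes: members reaching every carrier through descent, or
    # reaching all but their own co-parenting spouse (the spouse then joins
    # the apex couple as a carrier, not a transmission target)
    reach: dict[str, set[str]] = {}
    for c in carriers:
        for a in ped.ancestors(c):
            reach.setdefault(a, set()).add(c)
    candidates: dict[str, str | None] = {}
    for a, reached in reach.items():
        missing = set(carriers) - reached
        if not missing:
            candidates[a] = None
        elif len(missing) == 1 and a in carriers:
            # both spouses of a couple are carriers: they form the apex
            # jointly, provided some carrier actually descends from them
            (s,) = missing
            pairs = {ped.parents(k) for k in ped.children(a)}
            if any(p is not None and s in p for p in pairs):
                candidates[a] = s
    if not candidates:
        raise DisconnectedCarriersError(_carrier_partition(ped, carriers))

    costs: dict[str, tuple[set[tuple[str, str]], int]] = {}
    forced_partner: dict[str, str] = {}
    for apex, spouse in candidates.items():
        targets = [c for c in carriers if c != apex and c != spouse]
        if not targets:
            if spouse is not None:
                continue  # two spouses alone share no transmission path
            costs[apex] = (set(), 0)
        else:
            result = _min_union_edges(ped, apex, targets)
            if result is None:
                continue
            costs[apex] = result
        if spouse is not None:
            forced_partner[apex] = spouse
    if not costs:
        raise DisconnectedCarriersError(_carrier_partition(ped, carriers))
    best_cost = min(m for _, m in costs.values())
    tied = sorted(a for a, (_, m) in costs.items() if m == best_cost)

    def spouse_of(apex: str, edges: set[tuple[str, str]]) -> str | None:
        # the apex forms an introduction couple when every child it transmits
        # to has the same co-parent and that co-parent adds no extra meioses;
        # a carrier apex introduces on its own (the allele is known to be in
        # that individual, not merely somewhere in the couple)
        if apex in carriers:
            return None
        kids = [v for u, v in edges if u == apex]
        partners = set()
        for kid in kids:
            pair = ped.parents(kid)
            if pair is None:
                return None
            partners.add(pair[0] if pair[1] == apex else pair[1])
        if len(partners) == 1:
            (partner,) = partners
            if partner != apex and partner in costs and costs[partner][1] == best_cost:
                return partner
        return None

    # prefer an apex that forms a couple; then the smallest id
    chosen = None
    for apex in tied:
        if forced_partner.get(apex) or spouse_of(apex, costs[apex][0]):
            chosen = apex
            break
    if chosen is None:
        chosen = tied[0]
    edges, meioses = costs[chosen]
    partner = forced_partner.get(chosen) or spouse_of(chosen, edges)
    introducers = frozenset({chosen, partner} if partner else {chosen})

    tree_nodes = {chosen} | {v for _, v in edges}
    co_parents: dict[str, str] = {}
    for u, v in edges:
        pair = ped.parents(v)
        assert pair is not None
        other = pair[0] if pair[1] == u else pair[1]
        if other not in introducers:
            co_parents[v] = other
    nodes = tree_nodes | set(introducers) | set(co_parents.values())
    marry_in = frozenset(
        n for n in nodes if ped[n].is_founder and n not in introducers
    )
    return ConnectingSubgraph(
        family_id=ped.family_id,
        carriers=frozenset(carriers),
        nodes=frozenset(nodes),
        tree_edges=tuple(sorted(edges)),
        meioses=meioses,
        founder_introducers=introducers,
        marry_in=marry_in,
        co_parents=co_parents,
        tied_apexes=tuple(tied),
    )


def pairwise_meioses(ped: Pedigree, a: str, b: str) -> int:
    """Meioses separating two individuals along their minimal connecting path."""
    return connecting_subgraph(ped, [a, b]).meioses
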