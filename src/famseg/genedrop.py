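"""Monte Carlo gene dropping on pedigrees.

Founders receive two alleles i.i.d. Bernoulli(q); every non-founder receives
one uniformly chosen allele from each parent (single biallelic locus, no
linkage, no mutation).  The simulator estimates the probability of carrier
configurations over a target set of individuals and doubles as the null
genotype generator for synthetic data.

Reproducibility contract: a fixed ``(seed, key, n_reps)`` triple yields
bit-identical results.  The optional ``key`` (e.g. ``(family_id,
variant_id)``) derives an independent substream via ``SeedSequence`` so
cohort simulations are order-independent.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .pedigree import Pedigree

EVENTS = ("all_carry", "at_least_one", "all_given_one")


def keyed_seed_sequence(seed: int, key: Sequence[str] = ()) -> np.random.SeedSequence:
    """SeedSequence for ``seed`` on an independent stream selected by ``key``."""
    if not key:
        return np.random.SeedSequence(seed)
    digest = hashlib.sha256("\x1f".join(str(k) for k in key).encode()).digest()
    spawn = [int.from_bytes(digest[i : i + 4], "big") for i in range(0, 16, 4)]
    return np.random.SeedSequence(entropy=seed, spawn_key=spawn)


@dataclass(frozen=True)
class GeneDropEstimate:
    """Monte Carlo estimate of a carrier-configuration probability.

    ``p_hat = n_success / n_reps`` with a 95% Wilson score interval
    (Wald behaves badly at the near-zero probabilities typical of rare
    variants).  For ``event='all_given_one'`` the denominator ``n_reps`` is
    the count of replicates with at least one carrier, taken from the same
    replicate stream as the numerator.
    """

    n_reps: int
    n_success: int
    p_hat: float
    ci_low: float
    ci_high: float
    seed: int
    event: str

    @property
    def se(self) -> float:
        """Binomial standard error of ``p_hat``."""
        if self.n_reps == 0:
            return float("nan")
        return float(np.sqrt(self.p_hat * (1.0 - self.p_hat) / self.n_reps))


def _topological_members(ped: Pedigree) -> list[str]:
    # lexicographic tie-break fixes the RNG call order -> bit-exact runs
    return list(nx.lexicographical_topological_sort(ped.graph))


def _drop_block(
    ped: Pedigree,
    order: Sequence[str],
    q: float,
    rng: np.random.Generator,
    n: int,
) -> dict[str, np.ndarray]:
    """One block of ``n`` replicates; returns id -> (n, 2) allele array."""
    alleles: dict[str, np.ndarray] = {}
    for iid in order:
        pair = ped.parents(iid)
        if pair is None:
            alleles[iid] = rng.random((n, 2)) < q
        else:
            father, mother = pair
            pick_f = rng.integers(0, 2, n)
            pick_m = rng.integers(0, 2, n)
            rows = np.arange(n)
            alleles[iid] = np.stack(
                [alleles[father][rows, pick_f], alleles[mother][rows, pick_m]],
                axis=1,
            )
    return alleles


def simulate(
    ped: Pedigree,
    carriers: Iterable[str],
    q: float,
    n_reps: int,
    seed: int,
    event: str = "all_carry",
    key: Sequence[str] = (),
    block_size: int = 1_000_000,
) -> GeneDropEstimate:
    """Estimate the probability of ``event`` over ``carriers`` by gene dropping.

    Parameters
    ----------
    event : {'all_carry', 'at_least_one', 'all_given_one'}
        ``all_carry``: every carrier holds >= 1 copy.  ``at_least_one``: some
        carrier holds >= 1 copy.  ``all_given_one``: ratio of the two counts.
    key : sequence of str
        Optional stream key (family id, variant id) for order-independent
        cohort runs.
    """
    carriers = sorted(set(carriers))
    if not carriers:
        raise ValueError("carrier set is empty")
    for c in carriers:
        ped[c]
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"allele frequency {q} outside [0, 1]")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if event not in EVENTS:
        raise ValueError(f"event must be one of {EVENTS}")

    # only the ancestral closure of the carriers matters; prune the rest
    pruned = ped.subpedigree(carriers)
    order = _topological_members(pruned)
    rng = np.random.default_rng(keyed_seed_sequence(seed, key))

    n_all = 0
    n_any = 0
    remaining = n_reps
    while remaining > 0:
        n = min(remaining, block_size)
        alleles = _drop_block(pruned, order, q, rng, n)
        carry = np.stack([alleles[c].any(axis=1) for c in carriers], axis=1)
        n_all += int(carry.all(axis=1).sum())
        n_any += int(carry.any(axis=1).sum())
        remaining -= n

    if event == "all_carry":
        n_success, denom = n_all, n_reps
    elif event == "at_least_one":
        n_success, denom = n_any, n_reps
    else:
        n_success, denom = n_all, n_any
    if denom == 0:
        p_hat, lo, hi = float("nan"), float("nan"), float("nan")
    else:
        p_hat = n_success / denom
        lo, hi = proportion_confint(n_success, denom, alpha=0.05, method="wilson")
    return GeneDropEstimate(
        n_reps=denom,
        n_success=n_success,
        p_hat=float(p_hat),
        ci_low=float(lo),
        ci_high=float(hi),
        seed=seed,
        event=event,
    )


def drop_genotypes(
    ped: Pedigree,
    q: float,
    seed: int,
    key: Sequence[str] = (),
    founder_overrides: Mapping[str, int] | None = None,
) -> dict[str, int]:
    """One gene-drop realization; returns id -> copy number in {0, 1, 2}.

    ``founder_overrides`` pins selected founders' copy numbers (used to plant
    a single introduction); all other founders draw Hardy-Weinberg(q).
    Mendelian consistency is guaranteed by construction.
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"allele frequency {q} outside [0, 1]")
    overrides = dict(founder_overrides or {})
    founder_ids = ped.founders()
    for iid, copies in overrides.items():
        if iid not in founder_ids:
            raise ValueError(f"override target {iid!r} is not a founder")
        if copies not in (0, 1, 2):
            raise ValueError(f"copy number {copies} not in {{0,1,2}}")

    rng = np.random.default_rng(keyed_seed_sequence(seed, key))
    order = _topological_members(ped)
    alleles: dict[str, np.ndarray] = {}
    for iid in order:
        pair = ped.parents(iid)
        if pair is None:
            drawn = rng.random(2) < q
            if iid in overrides:
                copies = overrides[iid]
                drawn = np.array([copies >= 1, copies == 2])
            alleles[iid] = drawn
        else:
            father, mother = pair
            alleles[iid] = np.array(
                [
                    alleles[father][rng.integers(0, 2)],
                    alleles[mother][rng.integers(0, 2)],
                ]
            )
    return {iid: int(a.sum()) for iid, a in alleles.items()}
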