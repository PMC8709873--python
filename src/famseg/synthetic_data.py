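"""Synthetic pedigrees, affection statuses, and planted rare variants.

The generator emulates the statistical structure the analysis assumes: a
multi-generation extended family founded by one couple, growing as a
branching process in which every reproducing member mates a new marry-in
founder (monogamous, no within-pedigree mating, hence loop-free), with
affection assigned independently from sex-stratified population risks times
a per-lineage risk multiplier, and a single rare variant introduced by one
founder and dropped Mendelian-fashion through the family.

Every stochastic output is a pure function of ``SimConfig.seed`` (streams
are keyed per stage, so pedigree structure, affection, and genotypes are
independently reproducible).  A JSON "truth" sidecar records the ground
truth of each experiment — lineage membership, the introducer, the forced
transmission path — so recovery tests never re-derive it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from .aggregation import PopulationRates
from .genedrop import keyed_seed_sequence
from .pedigree import Individual, Pedigree, write_ped
from .variant_filter import VariantRecord, write_variant_tsv

#: sex-stratified lifetime cumulative risk of the affected phenotype
#: (suicide-mortality scale: a few percent for males, under one percent
#: for females — the order observed in high-burden US state populations)
DEFAULT_RATES = PopulationRates({"male": 0.025, "female": 0.007}, mode="cumulative")


class DegenerateConfigError(Exception):
    """The configuration can never produce grandchildren."""


@dataclass(frozen=True)
class PlantedVariant:
    """A single-founder introduction to drop through the family.

    ``penetrant_transmission`` forces the allele along the descent path to
    every affected descendant of the introducer — an upper-bound
    alternative regime whose outputs are flagged non-Mendelian-null in the
    sidecar.
    """

    introducer_founder: str | None = None  # default: the apex couple's male
    penetrant_transmission: bool = False


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic family.

    Defaults mirror the target design: 7 generations (extended high-risk
    families span 7-9), Poisson(2.5) offspring per mating (large historical
    families, kept tractable), sex-stratified lifetime risks, risk
    multiplier 1 (a null family; aggregation-recovery experiments plant
    10x), and a rare allele at population frequency 0.001.
    """

    n_generations: int = 7
    mean_offspring: float = 2.5
    offspring_dist: str = "poisson"  # or "fixed" (round(mean) per mating)
    base_rates: PopulationRates = field(default_factory=lambda: DEFAULT_RATES)
    risk_multiplier: float = 1.0
    q: float = 0.001
    planted_variant: PlantedVariant | None = None
    family_id: str = "FAM1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_generations < 2:
            raise ValueError("n_generations must be >= 2")
        if self.mean_offspring < 0:
            raise ValueError("mean_offspring must be >= 0")
        if self.offspring_dist not in ("poisson", "fixed"):
            raise ValueError("offspring_dist must be 'poisson' or 'fixed'")
        if self.risk_multiplier <= 0:
            raise ValueError("risk_multiplier must be positive")


def _offspring(cfg: SimConfig, rng: np.random.Generator) -> int:
    if cfg.offspring_dist == "fixed":
        return int(round(cfg.mean_offspring))
    return int(rng.poisson(cfg.mean_offspring))


def expected_member_count(cfg: SimConfig) -> float:
    """Analytic expected pedigree size of the branching process.

    Generation g of the blood lineage has mean size m^g; a member of a
    non-terminal generation acquires a marry-in spouse exactly when it has
    at least one child.
    """
    m = cfg.mean_offspring
    if cfg.offspring_dist == "fixed":
        m = float(round(m))
        p_reproduce = 1.0 if m >= 1 else 0.0
    else:
        p_reproduce = 1.0 - float(np.exp(-m))
    total = 2.0  # founder couple
    for g in range(1, cfg.n_generations):
        total += m**g
        if g <= cfg.n_generations - 2:
            total += m**g * p_reproduce
    return total


def generate_pedigree(cfg: SimConfig) -> tuple[Pedigree, dict]:
    """Branching-process extended family; returns (pedigree, truth sidecar).

    Raises :class:`DegenerateConfigError` for configurations that can never
    yield grandchildren; stochastic extinction of a particular draw is
    allowed — that family simply ends early.
    """
    if cfg.n_generations >= 3 and (
        cfg.mean_offspring == 0
        or (cfg.offspring_dist == "fixed" and round(cfg.mean_offspring) == 0)
    ):
        raise DegenerateConfigError(
            "mean_offspring yields zero grandchildren at n_generations >= 3"
        )
    rng = np.random.default_rng(keyed_seed_sequence(cfg.seed, ("pedigree",)))
    members: list[Individual] = [
        Individual(id="G0_A", sex="male", birth_year=1850, stratum="male",
                   genotyped=True, affected="unaffected"),
        Individual(id="G0_B", sex="female", birth_year=1850, stratum="female",
                   genotyped=True, affected="unaffected"),
    ]
    sex_of = {"G0_A": "male", "G0_B": "female"}
    lineage = ["G0_A", "G0_B"]
    marry_in: list[str] = []
    per_generation = [2]

    current = ["G0_A"]  # reproducing lineage members; gen 0 acts as a couple
    for gen in range(cfg.n_generations - 1):
        child_gen = gen + 1
        children: list[str] = []
        counter = 0
        for member_id in current:
            k = _offspring(cfg, rng)
            if k == 0:
                continue
            if gen == 0:
                male, female = "G0_A", "G0_B"
            else:
                spouse_id = member_id + "S"
                spouse_sex = "female" if sex_of[member_id] == "male" else "male"
                members.append(
                    Individual(id=spouse_id, sex=spouse_sex,
                               birth_year=1850 + 25 * gen, stratum=spouse_sex,
                               genotyped=True, affected="unaffected")
                )
                sex_of[spouse_id] = spouse_sex
                marry_in.append(spouse_id)
                male, female = (
                    (member_id, spouse_id)
                    if sex_of[member_id] == "male"
                    else (spouse_id, member_id)
                )
            for _ in range(k):
                counter += 1
                child_id = f"G{child_gen}_{counter:04d}"
                sex = "male" if rng.random() < 0.5 else "female"
                members.append(
                    Individual(id=child_id, father_id=male, mother_id=female,
                               sex=sex, birth_year=1850 + 25 * child_gen,
                               stratum=sex, genotyped=True,
                               affected="unaffected")
                )
                sex_of[child_id] = sex
                lineage.append(child_id)
                children.append(child_id)
        per_generation.append(len(children))
        current = children

    ped = Pedigree(cfg.family_id, members)
    truth = {
        "family_id": cfg.family_id,
        "seed": cfg.seed,
        "founder_couple": ["G0_A", "G0_B"],
        "lineage": sorted(lineage),
        "marry_in_founders": sorted(marry_in),
        "per_generation_lineage_counts": per_generation,
        "n_members": len(ped),
    }
    return ped, truth


def assign_affection(
    ped: Pedigree, cfg: SimConfig, truth: Mapping | None = None
) -> tuple[Pedigree, dict]:
    """Independent Bernoulli affection at stratum rate x lineage multiplier.

    Blood-lineage members (per ``truth``; by default the founder couple and
    its descendants) receive ``rate * risk_multiplier``; marry-in founders
    receive the base rate.  Raises ``ValueError`` when a multiplied
    probability exceeds 1.
    """
    if truth is not None:
        lineage = set(truth["lineage"])
    else:
        lineage = ped.descendants("G0_A", include_self=True) | {"G0_B"}
    rng = np.random.default_rng(keyed_seed_sequence(cfg.seed, ("affection",)))
    rates = cfg.base_rates
    new_members = []
    probs = {}
    for ind in ped:  # insertion order is deterministic
        p = rates.risk(ind.stratum)
        if ind.id in lineage:
            p *= cfg.risk_multiplier
        if p > 1.0:
            raise ValueError(
                f"affection probability {p} > 1 for {ind.id} "
                "(rate x risk_multiplier too large)"
            )
        probs[ind.id] = p
        status = "affected" if rng.random() < p else "unaffected"
        new_members.append(replace(ind, affected=status))
    out = Pedigree(ped.family_id, new_members)
    sidecar = {
        "family_id": ped.family_id,
        "seed": cfg.seed,
        "risk_multiplier": cfg.risk_multiplier,
        "lineage": sorted(lineage),
        "affection_probabilities": probs,
        "n_affected": sum(1 for i in out if i.affected == "affected"),
    }
    return out, sidecar


def plant_variant(
    ped: Pedigree, cfg: SimConfig
) -> tuple[dict[str, int], VariantRecord, dict]:
    """Drop one variant through the family; returns (genotypes, record, truth).

    With no ``cfg.planted_variant`` this is a pure null drop (every founder
    Hardy-Weinberg at ``cfg.q``).  With one, the introducer founder receives
    exactly one copy and the remaining founders draw the null; under
    ``penetrant_transmission`` the copy is additionally forced down the
    descent path to every affected descendant of the introducer, and the
    truth sidecar flags the realization as non-Mendelian-null and records
    the forced path (whose edge count is the true transmission meioses).
    """
    spec = cfg.planted_variant
    rng = np.random.default_rng(keyed_seed_sequence(cfg.seed, ("genedrop",)))
    founders = ped.founders()
    introducer = None
    if spec is not None:
        introducer = spec.introducer_founder or "G0_A"
        if introducer not in founders:
            raise ValueError(f"introducer {introducer!r} is not a founder")

    forced_edges: set[tuple[str, str]] = set()
    if spec is not None and spec.penetrant_transmission:
        import networkx as nx

        targets = [
            i.id
            for i in ped
            if i.affected == "affected"
            and i.id in ped.descendants(introducer, include_self=True)
        ]
        for t in targets:
            if t == introducer:
                continue
            path = nx.shortest_path(ped.graph, introducer, t)
            forced_edges |= {
                (path[i], path[i + 1]) for i in range(len(path) - 1)
            }

    # allele-level drop (deterministic call order: lexicographic topological)
    import networkx as nx

    order = list(nx.lexicographical_topological_sort(ped.graph))
    alleles: dict[str, tuple[bool, bool]] = {}
    for iid in order:
        pair = ped.parents(iid)
        if pair is None:
            a = (bool(rng.random() < cfg.q), bool(rng.random() < cfg.q))
            if iid == introducer:
                a = (True, False)
            alleles[iid] = a
        else:
            father, mother = pair
            inherited = []
            for parent in (father, mother):
                pa = alleles[parent]
                if (parent, iid) in forced_edges and any(pa):
                    inherited.append(True)  # take the variant copy
                else:
                    inherited.append(pa[rng.integers(0, 2)])
            alleles[iid] = (inherited[0], inherited[1])
    genotypes = {iid: int(a[0]) + int(a[1]) for iid, a in alleles.items()}
    carriers = sorted(i for i, g in genotypes.items() if g > 0)

    record = VariantRecord(
        chrom="2", pos=50_847_195, ref="G", alt="A",
        rsid="rs_synthetic", impact="MODERATE", sift="deleterious",
        polyphen="probably_damaging", consequence="missense",
        case_het=sum(1 for g in genotypes.values() if g == 1),
        case_hom=sum(1 for g in genotypes.values() if g == 2),
        case_n=len(genotypes),
    )
    truth = {
        "family_id": ped.family_id,
        "seed": cfg.seed,
        "q": cfg.q,
        "introducer": introducer,
        "penetrant_transmission": bool(spec and spec.penetrant_transmission),
        "mendelian_null": not (spec and spec.penetrant_transmission),
        "forced_path_edges": sorted(map(list, forced_edges)),
        "n_forced_meioses": len(forced_edges),
        "carriers": carriers,
    }
    return genotypes, record, truth


# ---------------------------------------------------------------------------
# Writers: PED + minimal VCFv4.2 (GT only) + annotation TSV + truth JSON
# ---------------------------------------------------------------------------

def write_vcf(
    path: str | Path,
    ped: Pedigree,
    genotypes: Mapping[str, int],
    record: VariantRecord,
) -> None:
    """Minimal single-record VCFv4.2 with GT-only FORMAT.

    Samples are the genotyped pedigree members in id order; annotation
    travels in INFO (IMPACT/SIFT/POLYPHEN/CSQTYPE) so the record round-trips
    through the VCF adapter in :mod:`famseg.variant_filter`.
    """
    samples = sorted(i.id for i in ped if i.genotyped)
    gt = {0: "0/0", 1: "0/1", 2: "1/1"}
    info_bits = []
    for key, value in (
        ("IMPACT", record.impact),
        ("SIFT", record.sift),
        ("POLYPHEN", record.polyphen),
        ("CSQTYPE", record.consequence),
    ):
        if value is not None:
            info_bits.append(f"{key}={value}")
    info = ";".join(info_bits) or "."
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={record.chrom}>",
        '##INFO=<ID=IMPACT,Number=1,Type=String,Description="Impact severity">',
        '##INFO=<ID=SIFT,Number=1,Type=String,Description="SIFT call">',
        '##INFO=<ID=POLYPHEN,Number=1,Type=String,Description="PolyPhen call">',
        '##INFO=<ID=CSQTYPE,Number=1,Type=String,Description="Consequence">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples),
        "\t".join(
            [
                record.chrom,
                str(record.pos),
                record.rsid or ".",
                record.ref,
                record.alt,
                ".",
                "PASS",
                info,
                "GT",
            ]
            + [gt[genotypes.get(s, 0)] for s in samples]
        ),
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def write_family_bundle(
    out_dir: str | Path,
    ped: Pedigree,
    genotypes: Mapping[str, int],
    record: VariantRecord,
    truth: Mapping,
    prefix: str | None = None,
) -> dict[str, Path]:
    """Write PED + VCF + annotation TSV + truth JSON for one family."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prefix = prefix or ped.family_id
    paths = {
        "ped": out_dir / f"{prefix}.ped",
        "vcf": out_dir / f"{prefix}.vcf",
        "annotation": out_dir / f"{prefix}.variants.tsv",
        "truth": out_dir / f"{prefix}.truth.json",
    }
    write_ped(ped, paths["ped"], extra_columns=("genotyped", "birth_year", "stratum"))
    write_vcf(paths["vcf"], ped, genotypes, record)
    write_variant_tsv([record], paths["annotation"])
    paths["truth"].write_text(json.dumps(dict(truth), indent=2, sort_keys=True) + "\n")
    return paths


def generate_cohort(
    n_families: int,
    cfg: SimConfig,
    risk_multiplier_for: Mapping[str, float] | None = None,
) -> tuple[list[Pedigree], dict]:
    """Generate ``n_families`` independent affection-assigned families.

    Family ``FAM<i>`` uses the substream keyed by its id, so the cohort is
    reproducible and order-independent.  ``risk_multiplier_for`` overrides
    the multiplier for selected family ids (planted-signal experiments).
    """
    cohort = []
    truths = {}
    for i in range(n_families):
        fam_id = f"FAM{i:05d}"
        mult = (risk_multiplier_for or {}).get(fam_id, cfg.risk_multiplier)
        fam_cfg = replace(
            cfg,
            family_id=fam_id,
            risk_multiplier=mult,
            seed=int(
                np.random.SeedSequence(
                    entropy=cfg.seed, spawn_key=(i,)
                ).generate_state(1)[0]
                % 2**31
            ),
        )
        ped, ped_truth = generate_pedigree(fam_cfg)
        ped, aff_truth = assign_affection(ped, fam_cfg, ped_truth)
        cohort.append(ped)
        truths[fam_id] = {"pedigree": ped_truth, "affection": aff_truth}
    return cohort, truths
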