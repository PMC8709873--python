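"""Rare functional variant prioritization and case-control arithmetic.

Two prioritization stages operate on annotated variant tables:

* :func:`family_shared_filter` — variants shared by all sequenced cases of
  one extended family, rare (< 0.01) in every control panel, and of
  MODERATE ("medium") or HIGH predicted impact.
* :func:`cohort_functional_filter` — cohort-wide screen for non-synonymous
  variants called damaging by both SIFT and PolyPhen, carried by at least
  five cases (case allele frequency >= 0.001) and rare (< 0.01) in every
  control panel.

Both attribute each elimination to the first failing rule in a fixed,
documented order, so the per-rule tallies in a :class:`FilterReport` sum to
the eliminated count.  Frequencies are compared at full precision; the
4-decimal rounding seen in reports is display only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

IMPACT_SYNONYMS = {
    "HIGH": "HIGH",
    "MEDIUM": "MODERATE",
    "MODERATE": "MODERATE",
    "MED": "MODERATE",
    "LOW": "LOW",
    "MODIFIER": "MODIFIER",
}
DAMAGING_POLYPHEN = ("probably_damaging", "possibly_damaging")


def normalize_impact(value: str) -> str:
    try:
        return IMPACT_SYNONYMS[value.strip().upper()]
    except (KeyError, AttributeError):
        raise ValueError(f"unknown impact severity {value!r}") from None


def allele_frequency(het: int, hom: int, n_individuals: int) -> float:
    """Minor-allele frequency from carrier counts: (het + 2*hom) / (2*n)."""
    if het < 0 or hom < 0:
        raise ValueError("carrier counts must be >= 0")
    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    if het + hom > n_individuals:
        raise ValueError("carriers exceed cohort size")
    return (het + 2 * hom) / (2 * n_individuals)


def display_frequency(freq: float) -> float:
    """The 4-decimal display convention used in reports."""
    return round(freq, 4)


@dataclass(frozen=True)
class VariantRecord:
    """One annotated biallelic variant with carrier and panel counts.

    ``control_panels`` maps panel name -> (allele count, allele number);
    rarity rules are conjunctive over ALL panels.  ``family_carrier_count``
    is the number of a target family's sequenced cases carrying the minor
    allele (used only by the family-shared stage).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    rsid: str | None = None
    impact: str | None = None
    sift: str | None = None  # deleterious / tolerated / None
    polyphen: str | None = None
    consequence: str | None = None  # missense / synonymous / other
    case_het: int = 0
    case_hom: int = 0
    case_n: int = 0
    control_panels: Mapping[str, tuple[int, int]] = field(default_factory=dict)
    family_carrier_count: int | None = None

    def __post_init__(self) -> None:
        if self.case_n and self.case_het + self.case_hom > self.case_n:
            raise ValueError(
                f"{self.variant_id}: carriers exceed cohort size"
            )
        for panel, (ac, an) in self.control_panels.items():
            if not 0 <= ac <= an:
                raise ValueError(
                    f"{self.variant_id}: bad allele counts for panel {panel!r}"
                )
        if self.impact is not None:
            object.__setattr__(self, "impact", normalize_impact(self.impact))

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}-{self.pos}-{self.ref}-{self.alt}"

    @property
    def case_carrier_count(self) -> int:
        """Carriers, not alleles: a homozygote counts once."""
        return self.case_het + self.case_hom

    @property
    def case_frequency(self) -> float:
        return allele_frequency(self.case_het, self.case_hom, self.case_n)

    def control_frequency(self, panel: str) -> float:
        ac, an = self.control_panels[panel]
        if an == 0:
            raise ValueError(f"panel {panel!r} has zero allele number")
        return ac / an


@dataclass(frozen=True)
class FilterReport:
    input_count: int
    surviving_count: int
    eliminated_by: Mapping[str, int]
    surviving: tuple[VariantRecord, ...]
    rule_order: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "input_count": self.input_count,
            "surviving_count": self.surviving_count,
            "eliminated_by": dict(self.eliminated_by),
            "rule_order": list(self.rule_order),
            "surviving": [r.variant_id for r in self.surviving],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.surviving:
            rows.append(
                {
                    "variant_id": rec.variant_id,
                    "rsid": rec.rsid,
                    "impact": rec.impact,
                    "sift": rec.sift,
                    "polyphen": rec.polyphen,
                    "consequence": rec.consequence,
                    "case_carriers": rec.case_carrier_count,
                    "case_frequency": display_frequency(rec.case_frequency)
                    if rec.case_n
                    else None,
                }
            )
        return pd.DataFrame(rows)


def _run_filter(
    records: Iterable[VariantRecord],
    rules: Sequence[tuple[str, Callable[[VariantRecord], bool | None]]],
) -> FilterReport:
    """Conjunction of predicates with first-fail attribution.

    A predicate returning ``None`` signals a missing annotation: the record
    is eliminated under the ``unannotated`` rule rather than raising.
    """
    records = list(records)
    eliminated: dict[str, int] = {}
    surviving: list[VariantRecord] = []
    for rec in records:
        verdict = "pass"
        for name, rule in rules:
            ok = rule(rec)
            if ok is None:
                verdict = "unannotated"
                break
            if not ok:
                verdict = name
                break
        if verdict == "pass":
            surviving.append(rec)
        else:
            eliminated[verdict] = eliminated.get(verdict, 0) + 1
    return FilterReport(
        input_count=len(records),
        surviving_count=len(surviving),
        eliminated_by=eliminated,
        surviving=tuple(surviving),
        rule_order=tuple(name for name, _ in rules),
    )


def _controls_rare(rec: VariantRecord, max_freq: float) -> bool | None:
    if not rec.control_panels:
        return None
    return all(
        rec.control_frequency(panel) < max_freq for panel in rec.control_panels
    )


def family_shared_filter(
    records: Iterable[VariantRecord],
    shared_in: int = 6,
    control_maf_max: float = 0.01,
    impacts: frozenset[str] = frozenset({"HIGH", "MODERATE"}),
) -> FilterReport:
    """Family stage: shared by all ``shared_in`` sequenced cases, rare in
    every control panel, MODERATE/HIGH impact.  Rule order: sharing ->
    impact -> control frequency."""
    impacts = frozenset(normalize_impact(i) for i in impacts)

    def rule_shared(rec: VariantRecord) -> bool | None:
        if rec.family_carrier_count is None:
            return None
        return rec.family_carrier_count == shared_in

    def rule_impact(rec: VariantRecord) -> bool | None:
        if rec.impact is None:
            return None
        return rec.impact in impacts

    return _run_filter(
        records,
        [
            ("shared_in_all_cases", rule_shared),
            ("impact", rule_impact),
            ("control_frequency", lambda r: _controls_rare(r, control_maf_max)),
        ],
    )


def cohort_functional_filter(
    records: Iterable[VariantRecord],
    min_case_freq: float = 0.001,
    max_control_freq: float = 0.01,
    min_carriers: int = 5,
) -> FilterReport:
    """Cohort stage: damaging non-synonymous variants at workable case
    frequency, rare in all control panels.

    The carrier-count and case-frequency rules are enforced independently
    (they coincide at the motivating cohort size but need not in general).
    Rule order: consequence -> annotations -> carriers -> case frequency ->
    control frequency.
    """

    def rule_consequence(rec: VariantRecord) -> bool | None:
        if rec.consequence is None:
            return None
        return rec.consequence == "missense"

    def rule_annotations(rec: VariantRecord) -> bool | None:
        if rec.sift is None or rec.polyphen is None:
            return None
        return rec.sift == "deleterious" and rec.polyphen in DAMAGING_POLYPHEN

    def rule_case_freq(rec: VariantRecord) -> bool | None:
        if rec.case_n <= 0:
            return None
        return rec.case_frequency >= min_case_freq

    return _run_filter(
        records,
        [
            ("consequence", rule_consequence),
            ("annotations", rule_annotations),
            ("carriers", lambda r: r.case_carrier_count >= min_carriers),
            ("case_frequency", rule_case_freq),
            ("control_frequency", lambda r: _controls_rare(r, max_control_freq)),
        ],
    )


def case_control_test(
    case_ac: int, case_an: int, control_ac: int, control_an: int
) -> tuple[float, float]:
    """Two-sided Fisher exact test on the 2x2 allele-count table.

    Returns ``(odds_ratio, p_value)``; the odds ratio uses the
    Haldane-Anscombe 0.5 correction when any cell is zero.
    """
    if not (0 <= case_ac <= case_an) or not (0 <= control_ac <= control_an):
        raise ValueError("allele counts inconsistent with allele numbers")
    if case_an == 0 or control_an == 0:
        raise ValueError("allele numbers must be positive")
    table = [
        [case_ac, case_an - case_ac],
        [control_ac, control_an - control_ac],
    ]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    cells = [c for row in table for c in row]
    if 0 in cells:
        a, b, c, d = (x + 0.5 for x in cells)
    else:
        a, b, c, d = cells
    return (a * d) / (b * c), float(p)


# ---------------------------------------------------------------------------
# Input adapters
# ---------------------------------------------------------------------------

TSV_COLUMNS = [
    "chrom", "pos", "ref", "alt", "rsid", "impact", "sift", "polyphen",
    "consequence", "case_het", "case_hom", "case_n",
]


def read_variant_tsv(path: str | Path) -> list[VariantRecord]:
    """Flat TSV adapter.

    Required columns: the :data:`TSV_COLUMNS` names; control panels appear
    as paired columns ``<panel>_ac`` / ``<panel>_an``; an optional
    ``family_carrier_count`` column feeds the family-shared stage.  Empty
    cells mean missing annotations.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"variant table missing columns: {missing}")
    panels = sorted(
        c[: -len("_ac")]
        for c in df.columns
        if c.endswith("_ac") and f"{c[:-3]}_an" in df.columns
    )
    records = []
    for _, row in df.iterrows():
        def opt(col):
            value = row.get(col)
            return None if pd.isna(value) else value
        control = {
            p: (int(row[f"{p}_ac"]), int(row[f"{p}_an"]))
            for p in panels
            if not pd.isna(row[f"{p}_ac"])
        }
        fcc = opt("family_carrier_count")
        records.append(
            VariantRecord(
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                ref=str(row["ref"]),
                alt=str(row["alt"]),
                rsid=opt("rsid"),
                impact=opt("impact"),
                sift=opt("sift"),
                polyphen=opt("polyphen"),
                consequence=opt("consequence"),
                case_het=int(row["case_het"]),
                case_hom=int(row["case_hom"]),
                case_n=int(row["case_n"]),
                control_panels=control,
                family_carrier_count=None if fcc is None else int(fcc),
            )
        )
    return records


def write_variant_tsv(records: Sequence[VariantRecord], path: str | Path) -> None:
    panels = sorted({p for r in records for p in r.control_panels})
    rows = []
    for r in records:
        row = {
            "chrom": r.chrom, "pos": r.pos, "ref": r.ref, "alt": r.alt,
            "rsid": r.rsid, "impact": r.impact, "sift": r.sift,
            "polyphen": r.polyphen, "consequence": r.consequence,
            "case_het": r.case_het, "case_hom": r.case_hom, "case_n": r.case_n,
            "family_carrier_count": r.family_carrier_count,
        }
        for p in panels:
            ac_an = r.control_panels.get(p)
            row[f"{p}_ac"] = None if ac_an is None else ac_an[0]
            row[f"{p}_an"] = None if ac_an is None else ac_an[1]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def records_with_carriers_from_vcf(
    path: str | Path, case_ids: Sequence[str] | None = None
) -> list[VariantRecord]:
    """Read a VCF and derive case carrier counts from GT fields.

    INFO keys ``IMPACT``, ``SIFT``, ``POLYPHEN``, ``CSQTYPE`` (consequence)
    are honoured when present.  Intended for the minimal GT-only VCFs this
    package writes; arbitrary production VCFs should be flattened to the
    TSV adapter upstream.
    """
    from cyvcf2 import VCF  # deferred: htslib import is comparatively slow

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    case_idx = [
        i for i, s in enumerate(samples) if case_ids is None or s in set(case_ids)
    ]
    records = []
    for v in vcf:
        types = v.gt_types  # 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        het = sum(1 for i in case_idx if types[i] == 1)
        hom = sum(1 for i in case_idx if types[i] == 3)
        info = dict(v.INFO)
        records.append(
            VariantRecord(
                chrom=str(v.CHROM),
                pos=int(v.POS),
                ref=v.REF,
                alt=v.ALT[0] if v.ALT else ".",
                rsid=v.ID,
                impact=info.get("IMPACT"),
                sift=info.get("SIFT"),
                polyphen=info.get("POLYPHEN"),
                consequence=info.get("CSQTYPE"),
                case_het=het,
                case_hom=hom,
                case_n=len(case_idx),
            )
        )
    return records


def with_family_carriers(
    record: VariantRecord, carrier_count: int
) -> VariantRecord:
    return replace(record, family_carrier_count=carrier_count)
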