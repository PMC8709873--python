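"""High-risk family ascertainment by observed-vs-expected affected counts.

A family is called high-risk when the number of affected members exceeds
what stratified population rates predict, judged by an exact one-sided
Poisson test on the expected count: with per-family expecteds typically
well below one, normal approximations to the standardized incidence ratio
(SIR = observed / expected) are invalid, while the Poisson upper tail
``P(X >= observed | mean = expected)`` is exact and conservative under
discreteness.  The ascertainment threshold is a nominal p < 0.01 with no
multiple-testing correction; Bonferroni-adjusted flags are reported as
supplementary output only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .pedigree import Pedigree

HIGH_RISK_ALPHA = 0.01


class RatesError(Exception):
    """A member's stratum does not resolve, or the rate table is invalid."""


@dataclass(frozen=True)
class PopulationRates:
    """Stratified population risk of the affected phenotype.

    ``mode='cumulative'``: ``strata`` maps stratum key -> lifetime cumulative
    risk per person (probability).  ``mode='person_year'``: stratum key ->
    rate per person-year; members then need years-at-risk.
    """

    strata: Mapping[str, float]
    mode: str = "cumulative"

    def __post_init__(self) -> None:
        if self.mode not in ("cumulative", "person_year"):
            raise RatesError(f"unknown rates mode {self.mode!r}")
        for key, value in self.strata.items():
            if self.mode == "cumulative" and not 0.0 <= value <= 1.0:
                raise RatesError(f"cumulative risk for {key!r} outside [0,1]")
            if value < 0.0:
                raise RatesError(f"negative rate for stratum {key!r}")

    def risk(self, stratum: str | None, years_at_risk: float | None = None) -> float:
        if stratum is None or stratum not in self.strata:
            raise RatesError(f"unresolvable stratum {stratum!r}")
        base = self.strata[stratum]
        if self.mode == "cumulative":
            return base
        if years_at_risk is None:
            raise RatesError(
                f"person_year mode requires years-at-risk (stratum {stratum!r})"
            )
        return base * years_at_risk

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PopulationRates":
        """Read a 3-column TSV: stratum, mode, value (one mode per table)."""
        df = pd.read_csv(path, sep="\t", names=["stratum", "mode", "value"],
                         header=None, comment="#", dtype={"stratum": str})
        modes = set(df["mode"])
        if len(modes) != 1:
            raise RatesError(f"mixed rate modes in table: {sorted(modes)}")
        return cls(dict(zip(df["stratum"], df["value"].astype(float))),
                   mode=modes.pop())

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for key in sorted(self.strata):
                fh.write(f"{key}\t{self.mode}\t{self.strata[key]!r}\n")


@dataclass(frozen=True)
class AggregationResult:
    family_id: str
    observed: int
    expected: float
    sir: float
    p_value: float
    high_risk: bool
    n_eligible: int = 0
    bonferroni_high_risk: bool | None = None

    def to_dict(self) -> dict:
        return {
            "family_id": self.family_id,
            "observed": self.observed,
            "expected": self.expected,
            "sir": self.sir,
            "p_value": self.p_value,
            "high_risk": self.high_risk,
            "n_eligible": self.n_eligible,
            "bonferroni_high_risk": self.bonferroni_high_risk,
        }


def expected_count(
    ped: Pedigree,
    rates: PopulationRates,
    years_at_risk: Mapping[str, float] | None = None,
) -> float:
    """Expected affected count: sum of member risks under population rates.

    Members of unknown affection status are excluded (they are excluded
    from the observed count too, so including them would bias the SIR).
    """
    total = 0.0
    n = 0
    for ind in ped:
        if ind.affected == "unknown":
            continue
        years = None if years_at_risk is None else years_at_risk.get(ind.id)
        try:
            total += rates.risk(ind.stratum, years)
        except RatesError as err:
            raise RatesError(f"member {ind.id!r}: {err}") from None
        n += 1
    if n == 0:
        raise ValueError(
            f"family {ped.family_id!r}: no members with known affection status"
        )
    return total


def observed_count(ped: Pedigree) -> int:
    return sum(1 for ind in ped if ind.affected == "affected")


def sir_test(observed: int, expected: float) -> tuple[float, float]:
    """Standardized incidence ratio and exact Poisson upper-tail p-value.

    Returns ``(sir, p)`` with ``sir = observed/expected`` and
    ``p = P(X >= observed)`` for ``X ~ Poisson(expected)``.
    """
    if expected <= 0.0:
        raise ValueError(f"expected count must be positive, got {expected}")
    if observed < 0:
        raise ValueError("observed count must be >= 0")
    p = float(stats.poisson.sf(observed - 1, expected))
    return observed / expected, p


def screen_families(
    cohort: Iterable[Pedigree],
    rates: PopulationRates,
    alpha: float = HIGH_RISK_ALPHA,
    years_at_risk: Mapping[str, Mapping[str, float]] | None = None,
) -> tuple[list[AggregationResult], dict[str, str]]:
    """Screen a cohort of families for familial aggregation.

    Returns results sorted ascending by p-value (ties by family id) plus a
    map of families that failed (family id -> error message); a failing
    family never aborts the screen.
    """
    cohort = list(cohort)
    if not cohort:
        raise ValueError("empty cohort")
    results: list[AggregationResult] = []
    failures: dict[str, str] = {}
    for ped in cohort:
        try:
            fam_years = None if years_at_risk is None else years_at_risk.get(
                ped.family_id
            )
            expected = expected_count(ped, rates, fam_years)
            observed = observed_count(ped)
            sir, p = sir_test(observed, expected)
        except (RatesError, ValueError) as err:
            failures[ped.family_id] = str(err)
            continue
        n_eligible = sum(1 for i in ped if i.affected != "unknown")
        results.append(
            AggregationResult(
                family_id=ped.family_id,
                observed=observed,
                expected=expected,
                sir=sir,
                p_value=p,
                high_risk=p < alpha,
                n_eligible=n_eligible,
            )
        )
    n_tests = len(results)
    results = [
        AggregationResult(
            **{**r.to_dict(), "bonferroni_high_risk": r.p_value < alpha / n_tests}
        )
        for r in results
    ]
    results.sort(key=lambda r: (r.p_value, r.family_id))
    return results, failures


def results_to_frame(results: Sequence[AggregationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])


def write_results(
    results: Sequence[AggregationResult],
    tsv_path: str | Path | None = None,
    json_path: str | Path | None = None,
) -> None:
    if tsv_path is not None:
        results_to_frame(results).to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        Path(json_path).write_text(
            json.dumps([r.to_dict() for r in results], indent=2, sort_keys=True)
            + "\n"
        )
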