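"""Health-economic aggregation: per-patient cost, PPP weighting, savings.

The annual per-patient cost combines the median direct treatment cost
across European country/treatment combinations (reference: EUR 565) with a
work-loss surcharge (reference ratio 0.185 between medical expenses and
absence from work), giving EUR 670 per patient and year.  Country totals
are weighted by purchasing-power-parity-adjusted health expenditure per
capita, normalised so that uniform weights reproduce patients x cost
exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .sensitisation import CountryRateTable

__all__ = [
    "EconParams",
    "CostSummary",
    "per_patient_cost",
    "median_treatment_cost",
    "ppp_weighted_costs",
    "scenario_savings",
]


@dataclass(frozen=True)
class EconParams:
    median_treatment_cost: float = 565.0  # EUR / patient / year
    work_loss_ratio: float = 0.185  # absence-from-work : medical-expense ratio
    ppp_reference: str = "patient_weighted_mean"  # or a country code as str(int)

    def __post_init__(self) -> None:
        if self.median_treatment_cost < 0 or self.work_loss_ratio < 0:
            raise ValueError("costs and ratios must be >= 0")


@dataclass
class CostSummary:
    """Annual costs by country plus the European total (EUR/year)."""

    by_country: dict[int, float]
    per_patient_cost: float

    @property
    def total(self) -> float:
        return float(sum(self.by_country.values()))

    def to_dict(self) -> dict:
        return {
            "per_patient_cost_eur": self.per_patient_cost,
            "total_eur_per_year": self.total,
            "by_country": {str(c): v for c, v in sorted(self.by_country.items())},
        }


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def per_patient_cost(params: EconParams = EconParams()) -> int:
    """Annual cost per patient in whole euros, rounded half-up.

    565 x (1 + 0.185) = 669.525 -> EUR 670 at the reference parameters.
    """
    return _round_half_up(params.median_treatment_cost * (1.0 + params.work_loss_ratio))


def median_treatment_cost(costs: pd.DataFrame, column: str = "cost_eur") -> float:
    """Median annual treatment cost over country/treatment combinations."""
    if costs.empty:
        raise ValueError("empty treatment-cost table")
    return float(costs[column].median())


def ppp_weighted_costs(
    patients_by_country: Mapping[int, float],
    cost: float,
    ppp: CountryRateTable,
    params: EconParams = EconParams(),
) -> CostSummary:
    """Country-level costs weighted by PPP-adjusted health expenditure.

    country cost = patients_c x cost x (ppp_c / ppp_ref).  The reference
    level ppp_ref is the patient-weighted mean weight by default, which
    makes the weighting self-normalising: uniform weights (or a single
    country) give exactly patients x cost, and rescaling all weights by a
    common factor changes nothing.
    """
    missing = sorted(c for c in patients_by_country if c not in ppp.ppp_weight)
    if missing:
        raise ValueError(f"ppp weight missing for countries: {missing}")
    total_patients = float(sum(patients_by_country.values()))
    if params.ppp_reference == "patient_weighted_mean":
        if total_patients > 0:
            ppp_ref = (
                sum(n * ppp.ppp_weight[c] for c, n in patients_by_country.items())
                / total_patients
            )
        else:
            ppp_ref = 1.0
    else:
        ref_code = int(params.ppp_reference)
        if ref_code not in ppp.ppp_weight:
            raise ValueError(f"reference country {ref_code} has no ppp weight")
        ppp_ref = ppp.ppp_weight[ref_code]
    by_country = {
        int(c): float(n) * cost * (ppp.ppp_weight[c] / ppp_ref)
        for c, n in patients_by_country.items()
    }
    return CostSummary(by_country=by_country, per_patient_cost=cost)


def scenario_savings(baseline: CostSummary, scenario: CostSummary) -> CostSummary:
    """Per-country and total savings: baseline minus scenario costs."""
    if set(baseline.by_country) != set(scenario.by_country):
        raise ValueError("baseline and scenario cover different country sets")
    diff = {c: baseline.by_country[c] - scenario.by_country[c] for c in baseline.by_country}
    return CostSummary(by_country=diff, per_patient_cost=baseline.per_patient_cost)
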