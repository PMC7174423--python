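"""End-to-end orchestration: baseline burden, beetle scenario, savings.

The baseline chains the spatial stages — station pollen integrals are
gridded, the two sensitisation layers multiplied, the clinical-relevance
and exposure corrections applied, patients counted per country and costed
with PPP weighting.  The scenario damps each cell's pollen by the
generation-dependent reduction fraction, re-applies the exposure
threshold, scales patients through the exposure-response elasticity, and
re-costs; savings are the exact per-country difference.  Lower/mean/upper
beetle suitability masks produce scenario bounds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .economics import CostSummary, EconParams, per_patient_cost, ppp_weighted_costs, scenario_savings
from .exposure_response import CommunityRecord, ElasticityResults
from .grids import RasterGrid
from .phenology import ReductionPolicy, VoltinismParams, generations_grid, reduction_grid
from .sensitisation import (
    CountryRateTable,
    ExposureThreshold,
    apply_exposure_mask,
    clinical_patients_grid,
    count_patients,
)

logger = logging.getLogger("ragweed.pipeline")

__all__ = [
    "BaselineInputs",
    "BurdenStage",
    "BurdenReport",
    "run_baseline",
    "run_scenario",
    "run_scenario_bounds",
    "validate_against_reimbursement",
]


@dataclass
class BaselineInputs:
    """In-memory inputs for the baseline burden computation."""

    pollen: RasterGrid
    sensitisation: RasterGrid
    population: RasterGrid
    country: RasterGrid
    rates: CountryRateTable
    threshold: ExposureThreshold = field(default_factory=ExposureThreshold)
    econ: EconParams = field(default_factory=EconParams)


@dataclass
class BurdenStage:
    """Patients and costs of one pipeline state (baseline or scenario)."""

    patients_grid: RasterGrid
    patients_by_country: dict[int, float]
    total_patients: float
    costs: CostSummary

    def to_dict(self) -> dict:
        return {
            "total_patients": self.total_patients,
            "patients_by_country": {str(c): v for c, v in sorted(self.patients_by_country.items())},
            "costs": self.costs.to_dict(),
        }


@dataclass
class BurdenReport:
    baseline: BurdenStage
    scenario: BurdenStage
    savings: CostSummary
    patient_reduction_pct: float
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "baseline": self.baseline.to_dict(),
            "scenario": self.scenario.to_dict(),
            "savings_eur_per_year": self.savings.total,
            "savings_by_country": {str(c): v for c, v in sorted(self.savings.by_country.items())},
            "patient_reduction_pct": self.patient_reduction_pct,
            "provenance": self.provenance,
        }

    def summary(self) -> str:
        b, s = self.baseline, self.scenario
        return "\n".join(
            [
                "Ragweed allergy burden report",
                f"  baseline patients : {b.total_patients:,.0f}",
                f"  baseline costs    : EUR {b.costs.total:,.0f} / year",
                f"  scenario patients : {s.total_patients:,.0f}"
                f"  ({self.patient_reduction_pct:.1f}% fewer)",
                f"  scenario costs    : EUR {s.costs.total:,.0f} / year",
                f"  savings           : EUR {self.savings.total:,.0f} / year",
            ]
        )


def _stage(
    patients: RasterGrid, country: RasterGrid, econ: EconParams, rates: CountryRateTable
) -> BurdenStage:
    by_country, total = count_patients(patients, country)
    cost = per_patient_cost(econ)
    costs = ppp_weighted_costs(by_country, cost, rates, econ)
    return BurdenStage(patients, by_country, total, costs)


def run_baseline(inp: BaselineInputs) -> BurdenStage:
    """Baseline patient numbers and costs prior to beetle establishment."""
    patients = clinical_patients_grid(
        inp.sensitisation, inp.population, inp.country, inp.rates
    )
    patients = apply_exposure_mask(patients, inp.pollen, inp.threshold)
    stage = _stage(patients, inp.country, inp.econ, inp.rates)
    logger.info(
        "baseline: %.0f patients, EUR %.3g/yr", stage.total_patients, stage.costs.total
    )
    return stage


def _relative_patients(reduction: np.ndarray, beta: float, projection: str) -> np.ndarray:
    if projection == "powerlaw":
        return np.where(reduction >= 1.0, 0.0, (1.0 - reduction) ** beta)
    if projection == "first_order":
        return np.clip(1.0 - beta * reduction, 0.0, None)
    raise ValueError(f"unknown projection form {projection!r}")


def run_scenario(
    inp: BaselineInputs,
    baseline: BurdenStage,
    reduction: RasterGrid,
    elasticity: float | ElasticityResults,
    projection: str = "powerlaw",
    reapply_threshold: bool = True,
) -> BurdenReport:
    """Beetle scenario: damp pollen per cell, rescale patients, re-cost.

    Cells whose reduced pollen falls below the exposure threshold
    contribute zero patients (config-switchable via ``reapply_threshold``);
    the rest scale by the configured projection of the elasticity fit.
    """
    beta = elasticity.beta if isinstance(elasticity, ElasticityResults) else float(elasticity)
    inp.pollen._check_same_spec(reduction)
    factor = _relative_patients(reduction.values, beta, projection)
    scen_patients = baseline.patients_grid.copy()
    scen_patients.values = scen_patients.values * factor
    if reapply_threshold:
        reduced_pollen = inp.pollen.copy()
        reduced_pollen.values = reduced_pollen.values * (1.0 - reduction.values)
        scen_patients = apply_exposure_mask(scen_patients, reduced_pollen, inp.threshold)
    stage = _stage(scen_patients, inp.country, inp.econ, inp.rates)
    savings = scenario_savings(baseline.costs, stage.costs)
    pct = (
        100.0 * (1.0 - stage.total_patients / baseline.total_patients)
        if baseline.total_patients > 0
        else 0.0
    )
    report = BurdenReport(
        baseline=baseline,
        scenario=stage,
        savings=savings,
        patient_reduction_pct=pct,
        provenance={"version": __version__, "projection": projection, "beta": beta},
    )
    logger.info(
        "scenario: %.0f patients (%.1f%% fewer), savings EUR %.3g/yr",
        stage.total_patients, pct, savings.total,
    )
    return report


def run_scenario_bounds(
    inp: BaselineInputs,
    baseline: BurdenStage,
    gdd: RasterGrid,
    plant_mask: RasterGrid,
    beetle_masks: Mapping[str, RasterGrid],
    elasticity: float | ElasticityResults,
    voltinism: VoltinismParams = VoltinismParams(),
    policy: ReductionPolicy = ReductionPolicy(),
    projection: str = "powerlaw",
) -> dict[str, BurdenReport]:
    """Scenario reports per suitability bound (lower / mean / upper masks).

    These are scenario bounds driven by the suitability confidence maps,
    not sampling confidence intervals.
    """
    gens = generations_grid(gdd, voltinism)
    out = {}
    for name, mask in beetle_masks.items():
        red = reduction_grid(gens, policy, mask, plant_mask)
        out[name] = run_scenario(inp, baseline, red, elasticity, projection)
    return out


def validate_against_reimbursement(
    patients: RasterGrid,
    population: RasterGrid,
    records: list[CommunityRecord],
    year_range,
) -> pd.DataFrame:
    """Predicted vs observed per-community patient proportions.

    Predicted: the pipeline's patients/population at the community centroid
    cell.  Observed: the community's mean reimbursed patients over its
    population.  The returned frame has one row per overlapping community
    plus attrs ``mean_predicted``, ``sd_predicted``, ``mean_observed``,
    ``sd_observed``.
    """
    from .exposure_response import average_by_community

    df = average_by_community(records, year_range)
    rows = []
    for r in df.itertuples(index=False):
        cell = patients.spec.cell_of(r.x, r.y)
        if cell is None:
            continue
        i, j = cell
        if patients.nodata_mask[i, j] or population.nodata_mask[i, j]:
            continue
        pop_cell = population.values[i, j]
        if pop_cell <= 0:
            continue
        rows.append(
            {
                "community_id": r.community_id,
                "predicted_proportion": patients.values[i, j] / pop_cell,
                "observed_proportion": r.patients / r.population,
            }
        )
    if not rows:
        raise ValueError("no communities overlap the patient grid")
    out = pd.DataFrame(rows)
    out.attrs["mean_predicted"] = float(out["predicted_proportion"].mean())
    out.attrs["sd_predicted"] = float(out["predicted_proportion"].std(ddof=1))
    out.attrs["mean_observed"] = float(out["observed_proportion"].mean())
    out.attrs["sd_observed"] = float(out["observed_proportion"].std(ddof=1))
    return out


def config_hash(cfg: Mapping) -> str:
    """Stable short hash of a configuration mapping, for provenance blocks."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
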