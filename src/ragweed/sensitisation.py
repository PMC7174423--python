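"""From sensitisation studies to a map of clinically relevant patients.

The sensitisation map is the cellwise product of two independently
interpolated study layers: (a) overall sensitisation rates in the general
population and (b) ragweed sensitisation rates among sensitised persons.
Multiplying by a population raster and a country-level clinical-relevance
rate yields patients per cell; cells with a very low seasonal pollen
integral (< 10 grains/m3 by default) are excluded from the patient count
because allergen exposure there is negligible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

from .grids import GridSpec, PointSample, RasterGrid, interpolate_idw

__all__ = [
    "StudyKind",
    "SensitisationStudy",
    "CountryRateTable",
    "ExposureThreshold",
    "grid_sensitisation",
    "clinical_patients_grid",
    "apply_exposure_mask",
    "count_patients",
]


class StudyKind(str, Enum):
    OVERALL = "overall"
    RAGWEED_GIVEN_SENSITISED = "ragweed_given_sensitised"


@dataclass(frozen=True)
class SensitisationStudy:
    """One georeferenced sensitisation study: a rate among ``n_tested`` persons."""

    id: str
    x: float
    y: float
    rate: float
    n_tested: int
    kind: StudyKind

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError(f"study {self.id!r}: rate {self.rate} outside [0, 1]")
        if self.n_tested < 1:
            raise ValueError(f"study {self.id!r}: n_tested must be >= 1")


@dataclass
class CountryRateTable:
    """Country-level scalars: clinical-relevance rates and PPP weights."""

    clinical_relevance: Mapping[int, float]
    ppp_weight: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for c, r in self.clinical_relevance.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"country {c}: clinical relevance {r} outside [0, 1]")
        for c, w in self.ppp_weight.items():
            if w <= 0:
                raise ValueError(f"country {c}: ppp weight must be > 0")


@dataclass(frozen=True)
class ExposureThreshold:
    """Minimum seasonal pollen integral (grains/m3) for exposure to count."""

    min_seasonal_integral: float = 10.0

    def __post_init__(self) -> None:
        if self.min_seasonal_integral < 0:
            raise ValueError("threshold must be >= 0")


def _study_points(studies: Sequence[SensitisationStudy], kind: StudyKind) -> list[PointSample]:
    if not studies:
        raise ValueError("empty study list")
    bad = [s.id for s in studies if s.kind != kind]
    if bad:
        raise ValueError(f"studies {bad} have kind != {kind.value}")
    return [PointSample(s.id, s.x, s.y, s.rate) for s in studies]


def grid_sensitisation(
    overall: Sequence[SensitisationStudy],
    conditional: Sequence[SensitisationStudy],
    spec: GridSpec,
    power: float = 2.0,
    k: int = 12,
) -> RasterGrid:
    """Ragweed sensitisation rate grid: product of the two study layers.

    Each layer is IDW-interpolated on its own (unweighted by ``n_tested``)
    and the product is clamped to [0, 1] — IDW cannot overshoot the data
    range, so the clamp only guards degenerate configurations.
    """
    g_overall = interpolate_idw(_study_points(overall, StudyKind.OVERALL), spec, power, k)
    g_cond = interpolate_idw(
        _study_points(conditional, StudyKind.RAGWEED_GIVEN_SENSITISED), spec, power, k
    )
    prod = g_overall * g_cond
    prod.values = np.clip(prod.values, 0.0, 1.0)
    return prod


def clinical_patients_grid(
    sens: RasterGrid,
    population: RasterGrid,
    country_grid: RasterGrid,
    rates: CountryRateTable,
) -> RasterGrid:
    """Patients per cell: sensitisation rate x population x clinical relevance.

    Every cell is attributed to exactly one country via ``country_grid``;
    the clinical-relevance correction is a country-level scalar multiply.
    """
    sens._check_same_spec(population)
    sens._check_same_spec(country_grid)
    codes = np.unique(country_grid.values[~country_grid.nodata_mask].astype(int))
    missing = sorted(int(c) for c in codes if int(c) not in rates.clinical_relevance)
    if missing:
        raise ValueError(f"clinical relevance rate missing for countries: {missing}")
    relevance = np.zeros(sens.spec.shape)
    cc = country_grid.values.astype(int)
    for c in codes:
        relevance[cc == c] = rates.clinical_relevance[int(c)]
    out = sens * population
    out.values = out.values * relevance
    out.nodata_mask |= country_grid.nodata_mask
    out.values[out.nodata_mask] = 0.0
    return out


def apply_exposure_mask(
    patients: RasterGrid, pollen: RasterGrid, thr: ExposureThreshold | float = ExposureThreshold()
) -> RasterGrid:
    """Zero patients wherever the seasonal pollen integral is below threshold.

    The comparison is strict (< threshold), and sub-threshold cells become
    zero rather than nodata: they contribute zero patients but remain part
    of the study area.
    """
    if not isinstance(thr, ExposureThreshold):
        thr = ExposureThreshold(float(thr))
    patients._check_same_spec(pollen)
    out = patients.copy()
    low = (pollen.values < thr.min_seasonal_integral) & ~pollen.nodata_mask
    out.values[low] = 0.0
    return out


def count_patients(
    patients: RasterGrid, country_grid: RasterGrid
) -> tuple[dict[int, float], float]:
    """Per-country patient totals and the grand total over valid cells."""
    patients._check_same_spec(country_grid)
    valid = ~patients.nodata_mask & ~country_grid.nodata_mask
    cc = country_grid.values.astype(int)
    totals: dict[int, float] = {}
    for c in np.unique(cc[valid]):
        totals[int(c)] = float(patients.values[valid & (cc == c)].sum())
    return totals, float(sum(totals.values()))
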