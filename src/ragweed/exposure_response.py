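"""Community-level exposure-response: patients as a power law of pollen.

Healthcare reimbursement data at the community level (313 communities in
the Rhone-Alpes region, 2007-2015) show that the number of treated patients
scales with the seasonal pollen integral.  After averaging each community
over the study years, the model

    ln(patients) = beta * ln(pollen) + eps

is fitted by least squares *without a constant*: forcing the fit through
the origin encodes that zero pollen implies zero pollen-induced patients.
The slope beta is the elasticity — the percent change in patients per
percent change in pollen — and drives all biocontrol projections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CommunityRecord",
    "ElasticityResults",
    "ExposureResponseModel",
    "average_by_community",
    "fit_loglog_origin",
    "percent_change_first_order",
    "relative_patients_powerlaw",
]


@dataclass(frozen=True)
class CommunityRecord:
    """One community-year: patients treated and seasonal pollen integral."""

    community_id: str
    x: float
    y: float
    year: int
    patients: float
    pollen_integral: float
    population: float

    def __post_init__(self) -> None:
        if self.patients < 0 or self.pollen_integral < 0:
            raise ValueError(f"{self.community_id}/{self.year}: negative count")
        if self.population <= 0:
            raise ValueError(f"{self.community_id}/{self.year}: population must be > 0")
        if self.patients > self.population:
            raise ValueError(f"{self.community_id}/{self.year}: patients > population")


def average_by_community(
    records: Iterable[CommunityRecord], year_range: Iterable[int]
) -> pd.DataFrame:
    """Average pollen and patients per community over the years in range.

    Years missing for a community are simply absent from its mean;
    communities with no record in the range are omitted.  Returns a frame
    with columns community_id, pollen, patients, population, x, y.
    """
    years = set(int(y) for y in year_range)
    if not years:
        raise ValueError("year_range is empty")
    rows = [
        {
            "community_id": r.community_id,
            "pollen": r.pollen_integral,
            "patients": r.patients,
            "population": r.population,
            "x": r.x,
            "y": r.y,
        }
        for r in records
        if r.year in years
    ]
    if not rows:
        return pd.DataFrame(
            columns=["community_id", "pollen", "patients", "population", "x", "y"]
        )
    df = pd.DataFrame(rows)
    return (
        df.groupby("community_id", as_index=False)
        .agg(
            pollen=("pollen", "mean"),
            patients=("patients", "mean"),
            population=("population", "mean"),
            x=("x", "first"),
            y=("y", "first"),
        )
        .sort_values("community_id", ignore_index=True)
    )


class ExposureResponseModel:
    """No-intercept log-log regression of patients on pollen.

    Parameters
    ----------
    pollen, patients
        Community-mean exposures and patient counts.  Pairs where either
        is <= 0 are excluded before taking logs (the model is undefined
        there); the number excluded is reported on the results object.
    """

    def __init__(self, pollen: Sequence[float], patients: Sequence[float]):
        pollen = np.asarray(pollen, dtype=float)
        patients = np.asarray(patients, dtype=float)
        if pollen.shape != patients.shape:
            raise ValueError("pollen and patients must have equal length")
        keep = (pollen > 0) & (patients > 0)
        self.n_excluded = int((~keep).sum())
        self.log_x = np.log(pollen[keep])
        self.log_y = np.log(patients[keep])
        if self.log_x.size < 2:
            raise ValueError("no positive observations")

    @classmethod
    def from_records(
        cls, records: Iterable[CommunityRecord], year_range: Iterable[int]
    ) -> "ExposureResponseModel":
        df = average_by_community(records, year_range)
        return cls(df["pollen"].to_numpy(), df["patients"].to_numpy())

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, pollen: str = "pollen", patients: str = "patients"
    ) -> "ExposureResponseModel":
        return cls(df[pollen].to_numpy(), df[patients].to_numpy())

    def fit(self) -> "ElasticityResults":
        """Closed-form no-intercept least squares on the log scale."""
        x, y = self.log_x, self.log_y
        sxx = float(np.dot(x, x))
        beta = float(np.dot(x, y)) / sxx
        resid = y - beta * x
        n = x.size
        s2 = float(np.dot(resid, resid)) / (n - 1)  # n-1 df: one slope
        se = math.sqrt(s2 / sxx)
        syy = float(np.dot(y, y))
        r2 = 1.0 - float(np.dot(resid, resid)) / syy if syy > 0 else float("nan")
        return ElasticityResults(
            model=self, beta=beta, se_beta=se, n_used=n, r_squared_uncentered=r2
        )


@dataclass
class ElasticityResults:
    """Fitted exposure-response elasticity with its uncertainty."""

    model: ExposureResponseModel | None
    beta: float
    se_beta: float
    n_used: int
    r_squared_uncentered: float

    def __post_init__(self) -> None:
        if self.n_used < 2:
            raise ValueError("elasticity fit needs n_used >= 2")
        if self.se_beta < 0:
            raise ValueError("se_beta must be >= 0")

    @property
    def n_excluded(self) -> int:
        return self.model.n_excluded if self.model is not None else 0

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        from scipy.stats import t

        q = t.ppf(1 - alpha / 2, self.n_used - 1)
        return (self.beta - q * self.se_beta, self.beta + q * self.se_beta)

    def percent_change(self, pollen_pct_change: float) -> float:
        """First-order elasticity reading: beta x (% change in pollen)."""
        return percent_change_first_order(self, pollen_pct_change)

    def relative_patients(self, reduction_fraction: float) -> float:
        """Power-law relative patient count after a pollen reduction."""
        return relative_patients_powerlaw(self, reduction_fraction)

    def summary(self) -> str:
        lo, hi = self.conf_int()
        lines = [
            "Exposure-response fit: ln(patients) = beta * ln(pollen)  (no constant)",
            f"  n used        : {self.n_used}  (excluded non-positive: {self.n_excluded})",
            f"  beta          : {self.beta:.4f}  (se {self.se_beta:.4f})",
            f"  95% CI        : [{lo:.4f}, {hi:.4f}]",
            f"  R2 (uncentred): {self.r_squared_uncentered:.4f}",
            f"  10% pollen decrease -> {self.percent_change(-10.0):.1f}% change in patients",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "beta": self.beta,
            "se_beta": self.se_beta,
            "n_used": self.n_used,
            "r_squared_uncentered": self.r_squared_uncentered,
            "n_excluded": self.n_excluded,
        }


def fit_loglog_origin(pairs: Iterable[tuple[float, float]]) -> ElasticityResults:
    """Functional form of :class:`ExposureResponseModel`: fit (pollen, patients) pairs."""
    arr = np.asarray(list(pairs), dtype=float)
    if arr.size == 0:
        raise ValueError("no positive observations")
    return ExposureResponseModel(arr[:, 0], arr[:, 1]).fit()


def percent_change_first_order(fit: ElasticityResults, pollen_pct_change: float) -> float:
    """Percent change in patients for a given percent change in pollen."""
    return fit.beta * pollen_pct_change


def relative_patients_powerlaw(fit: ElasticityResults, reduction_fraction: float) -> float:
    """Relative patients (1 - r)**beta after reducing pollen by fraction r.

    Exact under the fitted power law; agrees with the first-order reading
    for small r.  Returns 0 at r = 1 (eradication).
    """
    r = float(reduction_fraction)
    if not 0.0 <= r <= 1.0:
        raise ValueError("reduction fraction must lie in [0, 1]")
    if r == 1.0:
        return 0.0
    return float((1.0 - r) ** fit.beta)
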