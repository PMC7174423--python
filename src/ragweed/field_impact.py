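"""Field-experiment analysis: raceme production with and without the beetle.

Pollen production per plot is proxied by total raceme length, estimated
allometrically as

    r = n * m * exp(v * beta + alpha)

where n is the number of plants in the plot, m the fraction that matured,
v the mean log plant volume, and (alpha, beta) the site-treatment
regression of log raceme length on log volume.  Densities (cm raceme per
m^2) are then analysed with a hurdle model: a Bernoulli-logit part for
whether a plot produces racemes at all, and a Poisson-log part for the
positive densities, both with a Gaussian site random intercept fitted by
Laplace-approximated maximum likelihood and tested against their
no-treatment null models by likelihood ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import special, stats

from .glmm import GLMMResults, RandomInterceptGLMM, lr_test

__all__ = [
    "Treatment",
    "AllometrySample",
    "AllometryResults",
    "AllometryModel",
    "PlotRecord",
    "plot_raceme_density",
    "HurdleModel",
    "HurdleResults",
    "expected_density",
    "percent_production_reduction",
]


class Treatment(str, Enum):
    CONTROL = "control"  # beetle present
    BEETLE_EXCLUDED = "beetle_excluded"  # insecticide exclusion


@dataclass
class AllometrySample:
    """Plant-level (log volume, log total raceme length) pairs for one site-treatment."""

    site: str
    treatment: Treatment
    log_volume: np.ndarray
    log_raceme_length: np.ndarray

    def __post_init__(self) -> None:
        self.log_volume = np.asarray(self.log_volume, dtype=float)
        self.log_raceme_length = np.asarray(self.log_raceme_length, dtype=float)
        if self.log_volume.shape != self.log_raceme_length.shape:
            raise ValueError("allometry arrays must have equal length")
        if self.log_volume.size < 2:
            raise ValueError("allometry fit needs >= 2 plants")


@dataclass(frozen=True)
class AllometryResults:
    """Intercept and slope of log raceme length on log volume."""

    alpha: float
    beta: float
    site: str
    treatment: Treatment
    n: int = 0
    r_squared: float = float("nan")


class AllometryModel:
    """OLS of log raceme length on log plant volume for one site-treatment."""

    def __init__(self, sample: AllometrySample):
        if np.unique(sample.log_volume).size < 2:
            raise ValueError("degenerate allometry sample: log_volume is constant")
        self.sample = sample

    def fit(self) -> AllometryResults:
        X = sm.add_constant(self.sample.log_volume)
        res = sm.OLS(self.sample.log_raceme_length, X).fit()
        return AllometryResults(
            alpha=float(res.params[0]),
            beta=float(res.params[1]),
            site=self.sample.site,
            treatment=self.sample.treatment,
            n=int(res.nobs),
            r_squared=float(res.rsquared),
        )


@dataclass
class PlotRecord:
    """End-of-season state of one 0.5 x 0.5 m experimental plot."""

    plot_id: str
    site: str
    treatment: Treatment
    n_plants: int
    frac_matured: float
    mean_log_volume: float | None  # None: use the site-treatment mean
    plot_area: float = 0.25  # m^2
    excluded: bool = False  # e.g. no plants in the establishment year

    def __post_init__(self) -> None:
        if self.n_plants < 0:
            raise ValueError(f"plot {self.plot_id}: n_plants < 0")
        if not 0.0 <= self.frac_matured <= 1.0:
            raise ValueError(f"plot {self.plot_id}: frac_matured outside [0, 1]")
        if self.plot_area <= 0:
            raise ValueError(f"plot {self.plot_id}: plot_area must be > 0")


def plot_raceme_density(
    rec: PlotRecord,
    fit: AllometryResults,
    site_treatment_mean_v: float | None = None,
) -> float:
    """Raceme density of a plot in cm per m^2.

    r = n * m * exp(v * beta + alpha), rescaled by the plot area.  When the
    plot has no measured volume, the site-treatment mean volume is used.
    """
    if rec.n_plants == 0 or rec.frac_matured == 0.0:
        return 0.0
    v = rec.mean_log_volume
    if v is None:
        if site_treatment_mean_v is None:
            raise ValueError(
                f"plot {rec.plot_id}: no measured volume and no site-treatment mean supplied"
            )
        v = site_treatment_mean_v
    r = rec.n_plants * rec.frac_matured * math.exp(v * fit.beta + fit.alpha)
    return r / rec.plot_area


# ---------------------------------------------------------------------------
# Hurdle model
# ---------------------------------------------------------------------------

@dataclass
class HurdlePartFit:
    """One part (binomial or positive-Poisson) of the hurdle fit."""

    glmm: GLMMResults | None
    response_by_treatment: dict[Treatment, float]
    ci_by_treatment: dict[Treatment, tuple[float, float]]
    sigma_site: float
    loglik: float
    lrt_chi2: float
    lrt_pvalue: float
    degenerate: bool = False  # e.g. all plots produced racemes
    boundary: bool = False


@dataclass
class HurdleResults:
    """Hurdle-model estimates: production probability x positive density."""

    binomial: HurdlePartFit
    positive: HurdlePartFit
    n_plots: int
    n_positive: int

    @property
    def p_produce(self) -> dict[Treatment, float]:
        return self.binomial.response_by_treatment

    @property
    def mean_positive_density(self) -> dict[Treatment, float]:
        return self.positive.response_by_treatment

    def expected_density(self, treatment: Treatment) -> float:
        """Unconditional expected raceme density: p(produce) x E[density | > 0]."""
        return (
            self.p_produce[treatment] * self.mean_positive_density[treatment]
        )

    def percent_reduction(self) -> float:
        """Percent drop in expected production attributable to the beetle."""
        e_ctrl = self.expected_density(Treatment.CONTROL)
        e_excl = self.expected_density(Treatment.BEETLE_EXCLUDED)
        if e_excl == 0:
            raise ValueError("expected density without beetle is zero; reduction undefined")
        return 100.0 * (1.0 - e_ctrl / e_excl)

    def summary(self) -> str:
        def part(name: str, p: HurdlePartFit, fmt: str) -> list[str]:
            lines = [f"{name} part (sigma_site {p.sigma_site:.3f}):"]
            for t in (Treatment.CONTROL, Treatment.BEETLE_EXCLUDED):
                lo, hi = p.ci_by_treatment.get(t, (float("nan"), float("nan")))
                lines.append(
                    f"  {t.value:<16s} {p.response_by_treatment[t]:{fmt}}"
                    f"  (95% CI {lo:{fmt}}-{hi:{fmt}})"
                )
            tag = " [degenerate]" if p.degenerate else (" [boundary]" if p.boundary else "")
            lines.append(
                f"  LRT vs null: chi2(1) = {p.lrt_chi2:.3f}, p = {p.lrt_pvalue:.4g}{tag}"
            )
            return lines

        out = [f"Hurdle model on {self.n_plots} plots ({self.n_positive} producing racemes)"]
        out += part("Production probability", self.binomial, ".3f")
        out += part("Positive raceme density (cm/m^2)", self.positive, ".1f")
        for t in (Treatment.CONTROL, Treatment.BEETLE_EXCLUDED):
            out.append(
                f"Expected density, {t.value}: {self.expected_density(t):.1f} cm/m^2"
            )
        return "\n".join(out)


class HurdleModel:
    """Two-part mixed model for plot-level raceme density.

    Parameters
    ----------
    data
        Frame with columns ``site``, ``treatment`` and ``density``
        (cm raceme per m^2).  Densities are rounded half-up to integer
        counts for the Poisson part.  Rows flagged ``excluded`` (optional
        column) are dropped.
    """

    def __init__(self, data: pd.DataFrame):
        d = data.copy()
        if "excluded" in d.columns:
            d = d[~d["excluded"].astype(bool)]
        for col in ("site", "treatment", "density"):
            if col not in d.columns:
                raise ValueError(f"hurdle data missing column {col!r}")
        d["treatment"] = d["treatment"].map(lambda t: Treatment(t))
        present = set(d["treatment"])
        if present != {Treatment.CONTROL, Treatment.BEETLE_EXCLUDED}:
            raise ValueError("both treatments must be present")
        if d["site"].nunique() < 2:
            raise ValueError("hurdle model needs >= 2 sites")
        self.data = d.reset_index(drop=True)

    @staticmethod
    def _design(d: pd.DataFrame) -> np.ndarray:
        excl = (d["treatment"] == Treatment.BEETLE_EXCLUDED).to_numpy(float)
        return np.column_stack([np.ones(len(d)), excl])

    @staticmethod
    def _responses(glmm: GLMMResults, family: str) -> tuple[dict, dict]:
        inv = special.expit if family == "binomial" else np.exp
        vals, cis = {}, {}
        for t, x in ((Treatment.CONTROL, [1.0, 0.0]), (Treatment.BEETLE_EXCLUDED, [1.0, 1.0])):
            eta = glmm.predict_linear(x)
            vals[t] = float(inv(eta))
            if glmm.cov_params is not None:
                xv = np.zeros(glmm.cov_params.shape[0])
                xv[: len(x)] = x
                se = math.sqrt(max(0.0, xv @ glmm.cov_params @ xv))
                with np.errstate(over="ignore"):
                    cis[t] = (float(inv(eta - 1.96 * se)), float(inv(eta + 1.96 * se)))
            else:
                cis[t] = (float("nan"), float("nan"))
        return vals, cis

    def _fit_part(
        self, d: pd.DataFrame, y: np.ndarray, family: str, random_effect: bool
    ) -> HurdlePartFit:
        # degenerate binomial part: no zeros (or no ones) at all
        if family == "binomial" and (y.min() == y.max()):
            p = float(y[0])
            t_vals = {Treatment.CONTROL: p, Treatment.BEETLE_EXCLUDED: p}
            t_cis = {t: (p, p) for t in t_vals}
            return HurdlePartFit(
                glmm=None,
                response_by_treatment=t_vals,
                ci_by_treatment=t_cis,
                sigma_site=0.0,
                loglik=0.0,
                lrt_chi2=float("nan"),
                lrt_pvalue=float("nan"),
                degenerate=True,
            )
        X = self._design(d)
        full = RandomInterceptGLMM(
            y, X, d["site"], family=family, exog_names=["intercept", "beetle_excluded"]
        ).fit(random_effect=random_effect)
        null = RandomInterceptGLMM(
            y, X[:, :1], d["site"], family=family, exog_names=["intercept"]
        ).fit(random_effect=random_effect)
        chi2, pval = lr_test(full, null, df=1)
        vals, cis = self._responses(full, family)
        return HurdlePartFit(
            glmm=full,
            response_by_treatment=vals,
            ci_by_treatment=cis,
            sigma_site=full.sigma,
            loglik=full.loglik,
            lrt_chi2=chi2,
            lrt_pvalue=pval,
            boundary=full.boundary,
        )

    def fit(self, random_effect: bool = True) -> HurdleResults:
        d = self.data
        produced = (d["density"] > 0).to_numpy(float)
        binom = self._fit_part(d, produced, "binomial", random_effect)

        pos = d[d["density"] > 0]
        counts = np.floor(pos["density"].to_numpy(float) + 0.5)  # cm/m^2, half-up
        poisson = self._fit_part(pos, counts, "poisson", random_effect)
        return HurdleResults(
            binomial=binom,
            positive=poisson,
            n_plots=len(d),
            n_positive=len(pos),
        )


def expected_density(fit: HurdleResults, treatment: Treatment | str) -> float:
    return fit.expected_density(Treatment(treatment))


def percent_production_reduction(
    per_year: Iterable[HurdleResults | tuple[float, float]],
) -> float:
    """Mean percent reduction in expected raceme production across years.

    Each element is either a fitted :class:`HurdleResults` or a pair
    ``(expected_control, expected_excluded)`` for years where the hurdle
    model is degenerate (e.g. no control plot produced racemes: that year
    contributes 100%).
    """
    pcts = []
    for item in per_year:
        if isinstance(item, HurdleResults):
            pcts.append(item.percent_reduction())
        else:
            e_ctrl, e_excl = float(item[0]), float(item[1])
            if e_excl == 0:
                raise ValueError("expected density without beetle is zero; reduction undefined")
            pcts.append(100.0 * (1.0 - e_ctrl / e_excl))
    if not pcts:
        raise ValueError("no yearly estimates supplied")
    return float(np.mean(pcts))
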