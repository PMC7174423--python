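"""Seeded synthetic inputs with known ground truth for every pipeline stage.

The real observational inputs (station pollen integrals, sensitisation
studies, community reimbursement records, Milan daily pollen, field-plot
data) are restricted, so every stage is exercised against generated data
whose true parameters are known.  Each generator draws from its own
pseudo-random stream derived from the master seed by a fixed offset, so
adding a generator never perturbs the others, and every generator is a
pure function of its configuration: identical seeds give bit-identical
output.

Defaults mirror the study conditions: 313 communities over 9 years with
elasticity 0.84 and log-noise 0.3; two study layers of 50 and 80 studies;
three field sites with 14 plots per site-treatment and one site lacking
the exclusion treatment, hurdle truth {0.26, 0.84, 260, 905}; voltinism
truth 288.7 GDD above 13.3 degC; pre-arrival mean daily pollen 46.2
grains/m3 with a level-dependent reduction tapering to 0.837.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .exposure_response import CommunityRecord
from .field_impact import AllometrySample, Treatment
from .grids import GridSpec, PointSample, RasterGrid
from .phenology import CohortRecord, DailyTemperatureSeries, VoltinismParams
from .sensitisation import CountryRateTable, SensitisationStudy, StudyKind

__all__ = [
    "SyntheticConfig",
    "gen_pollen_surface",
    "gen_sensitisation_studies",
    "gen_population",
    "gen_countries",
    "gen_community_health",
    "gen_daily_temps",
    "gen_cohorts",
    "gen_plot_data",
    "gen_prepost_pollen",
    "gen_suitability_masks",
    "gen_generations_inputs",
]

# fixed per-generator stream offsets
_STREAMS = {
    "pollen": 1,
    "studies": 2,
    "population": 3,
    "countries": 4,
    "communities": 5,
    "temps": 6,
    "plots": 7,
    "prepost": 8,
    "suitability": 9,
    "gdd": 10,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int = 0
    grid: GridSpec = field(
        default_factory=lambda: GridSpec(origin_x=0.0, origin_y=200_000.0, n_rows=20, n_cols=25)
    )
    # pollen surface
    n_stations: int = 100
    n_hotspots: int = 3
    background_pollen: float = 20.0
    hotspot_amplitude: tuple[float, float] = (800.0, 4000.0)
    station_noise_sigma_log: float = 0.2
    # sensitisation studies
    n_studies_overall: int = 50
    n_studies_conditional: int = 80
    # community health panel
    n_communities: int = 313
    years: tuple[int, ...] = tuple(range(2007, 2016))
    true_elasticity: float = 0.84
    noise_sigma_log: float = 0.3
    # geometric mean of the non-pollen multiplier must be 1 for the
    # through-origin log-log fit to be unbiased; keep the scale at 1 unless
    # deliberately probing that sensitivity
    community_scale: float = 1.0
    community_pop_median: float = 20_000.0
    community_pop_sigma_log: float = 0.5
    # countries / economics
    n_countries: int = 6
    # field plots (hurdle truth)
    p_control: float = 0.26
    p_excluded: float = 0.84
    mu_control: float = 260.0
    mu_excluded: float = 905.0
    site_sigma_logit: float = 0.3
    site_sigma_log: float = 0.1
    plots_per_site_treatment: int = 14
    allometry_alpha: float = 1.2
    allometry_beta: float = 0.9
    allometry_sigma: float = 0.25
    # voltinism
    voltinism: VoltinismParams = field(default_factory=VoltinismParams)
    lapse_rate: float = -6.5  # degC per km altitude
    temp_amplitude: float = 9.0
    temp_mean: float = 14.0
    temp_noise_sigma: float = 1.5
    diurnal_range: float = 8.0
    # pre/post Milan-like series
    prepost_stations: int = 3
    pre_target_mean: float = 46.2
    post_target_mean: float | None = None  # if set, post rescaled to this mean
    reduction_early: float = 0.90
    reduction_late: float = 0.837
    prepost_noise_sigma_log: float = 0.05


# ---------------------------------------------------------------------------
# Pollen surface and stations
# ---------------------------------------------------------------------------

def _surface_values(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    xs, ys = cfg.grid.cell_centres()
    extent_x = cfg.grid.n_cols * cfg.grid.cell_size
    extent_y = cfg.grid.n_rows * cfg.grid.cell_size
    vals = np.full(cfg.grid.shape, cfg.background_pollen)
    lo, hi = cfg.hotspot_amplitude
    for _ in range(cfg.n_hotspots):
        cx = cfg.grid.origin_x + rng.uniform(0.15, 0.85) * extent_x
        cy = cfg.grid.origin_y - rng.uniform(0.15, 0.85) * extent_y
        amp = rng.uniform(lo, hi)
        width = rng.uniform(0.1, 0.25) * min(extent_x, extent_y)
        vals += amp * np.exp(-((xs - cx) ** 2 + (ys - cy) ** 2) / (2 * width**2))
    return np.clip(vals, 0.0, None)


def gen_pollen_surface(cfg: SyntheticConfig) -> tuple[RasterGrid, list[PointSample]]:
    """True seasonal-pollen surface (smooth hot-spots on a low background)
    plus noisy station readings of it at distinct random cells."""
    rng = _rng(cfg.seed, "pollen")
    truth = RasterGrid(cfg.grid, _surface_values(cfg, rng))
    n_cells = cfg.grid.n_rows * cfg.grid.n_cols
    cells = rng.choice(n_cells, size=min(cfg.n_stations, n_cells), replace=False)
    xs, ys = cfg.grid.cell_centres()
    stations = []
    for s, flat in enumerate(cells):
        i, j = divmod(int(flat), cfg.grid.n_cols)
        noise = math.exp(rng.normal(0.0, cfg.station_noise_sigma_log))
        stations.append(
            PointSample(f"station_{s:03d}", float(xs[i, j]), float(ys[i, j]),
                        float(truth.values[i, j] * noise))
        )
    return truth, stations


# ---------------------------------------------------------------------------
# Sensitisation studies
# ---------------------------------------------------------------------------

def default_overall_rate(cfg: SyntheticConfig) -> Callable[[float, float], float]:
    """Smooth overall-sensitisation-rate field in [0.15, 0.45]."""
    ex = cfg.grid.n_cols * cfg.grid.cell_size
    ey = cfg.grid.n_rows * cfg.grid.cell_size

    def f(x: float, y: float) -> float:
        u = (x - cfg.grid.origin_x) / ex
        v = (cfg.grid.origin_y - y) / ey
        return 0.30 + 0.15 * math.sin(math.pi * u) * math.cos(math.pi * v / 2)

    return f


def default_conditional_rate(cfg: SyntheticConfig) -> Callable[[float, float], float]:
    """Smooth ragweed-given-sensitised field in [0.05, 0.65] (east-west gradient)."""
    ex = cfg.grid.n_cols * cfg.grid.cell_size

    def f(x: float, y: float) -> float:
        u = (x - cfg.grid.origin_x) / ex
        return 0.05 + 0.6 * u

    return f


def gen_sensitisation_studies(
    cfg: SyntheticConfig,
    overall_truth: Callable[[float, float], float] | None = None,
    conditional_truth: Callable[[float, float], float] | None = None,
) -> tuple[list[SensitisationStudy], list[SensitisationStudy]]:
    """Binomially sampled studies of the two truth fields at random locations."""
    rng = _rng(cfg.seed, "studies")
    overall_truth = overall_truth or default_overall_rate(cfg)
    conditional_truth = conditional_truth or default_conditional_rate(cfg)
    ex = cfg.grid.n_cols * cfg.grid.cell_size
    ey = cfg.grid.n_rows * cfg.grid.cell_size

    def draw(n: int, truth: Callable, kind: StudyKind, tag: str) -> list[SensitisationStudy]:
        out = []
        for s in range(n):
            x = cfg.grid.origin_x + rng.uniform(0, ex)
            y = cfg.grid.origin_y - rng.uniform(0, ey)
            n_tested = int(rng.integers(150, 2000))
            rate_true = min(1.0, max(0.0, truth(x, y)))
            rate = rng.binomial(n_tested, rate_true) / n_tested
            out.append(SensitisationStudy(f"{tag}_{s:03d}", x, y, rate, n_tested, kind))
        return out

    overall = draw(cfg.n_studies_overall, overall_truth, StudyKind.OVERALL, "ov")
    conditional = draw(
        cfg.n_studies_conditional, conditional_truth,
        StudyKind.RAGWEED_GIVEN_SENSITISED, "cond",
    )
    return overall, conditional


# ---------------------------------------------------------------------------
# Population, countries, economics tables
# ---------------------------------------------------------------------------

def gen_population(cfg: SyntheticConfig) -> RasterGrid:
    """Lognormal rural population field with a handful of city bumps."""
    rng = _rng(cfg.seed, "population")
    base = np.exp(rng.normal(8.0, 1.0, size=cfg.grid.shape))
    xs, ys = cfg.grid.cell_centres()
    for _ in range(4):
        cx = rng.uniform(xs.min(), xs.max())
        cy = rng.uniform(ys.min(), ys.max())
        width = 1.5 * cfg.grid.cell_size
        base += rng.uniform(2e5, 1e6) * np.exp(
            -((xs - cx) ** 2 + (ys - cy) ** 2) / (2 * width**2)
        )
    return RasterGrid(cfg.grid, base)


def gen_countries(cfg: SyntheticConfig) -> tuple[RasterGrid, CountryRateTable]:
    """Voronoi country partition of random capitals + per-country rate tables."""
    rng = _rng(cfg.seed, "countries")
    xs, ys = cfg.grid.cell_centres()
    capitals = np.column_stack([
        rng.uniform(xs.min(), xs.max(), size=cfg.n_countries),
        rng.uniform(ys.min(), ys.max(), size=cfg.n_countries),
    ])
    pts = np.column_stack([xs.ravel(), ys.ravel()])
    d2 = ((pts[:, None, :] - capitals[None, :, :]) ** 2).sum(axis=2)
    codes = d2.argmin(axis=1).reshape(cfg.grid.shape).astype(float) + 1
    clinical = {c + 1: float(rng.uniform(0.5, 0.9)) for c in range(cfg.n_countries)}
    ppp = {c + 1: float(rng.uniform(0.5, 2.0)) for c in range(cfg.n_countries)}
    return RasterGrid(cfg.grid, codes), CountryRateTable(clinical, ppp)


def default_treatment_costs() -> pd.DataFrame:
    """Synthetic nine-country annual treatment-cost table (EUR/patient/year).

    Stand-in for the published country cost compilation: spans the reported
    extremes (8.30 for antihistamines up to 8060 for asthma treatment) with
    median 565.  The pipeline computes the median from this table at run
    time rather than hard-coding it.
    """
    rows = [
        ("CZ", "antihistamines", 8.30),
        ("HU", "antihistamines", 95.0),
        ("FR", "rhinitis_treatment", 210.0),
        ("IT", "rhinitis_treatment", 410.0),
        ("DE", "rhinitis_treatment", 565.0),
        ("AT", "asthma_treatment", 820.0),
        ("NL", "asthma_treatment", 1450.0),
        ("SE", "asthma_treatment", 3600.0),
        ("CH", "asthma_treatment", 8060.0),
    ]
    return pd.DataFrame(rows, columns=["country", "treatment", "cost_eur"])


# ---------------------------------------------------------------------------
# Community health panel
# ---------------------------------------------------------------------------

def gen_community_health(
    cfg: SyntheticConfig, pollen_surface: RasterGrid
) -> list[CommunityRecord]:
    """Community-year panel with patients ~ scale * pollen^beta * pop/1e5 * eps.

    The multiplicative components other than pollen^beta (the scale, the
    population term and the lognormal noise) all have geometric mean one at
    the defaults, so the no-intercept log-log fit is unbiased for beta.
    """
    rng = _rng(cfg.seed, "communities")
    xs, ys = cfg.grid.cell_centres()
    flat_vals = pollen_surface.values.ravel()
    ok = np.flatnonzero(flat_vals > 0)
    cells = rng.choice(ok, size=cfg.n_communities, replace=True)
    records: list[CommunityRecord] = []
    for c, flat in enumerate(cells):
        i, j = divmod(int(flat), cfg.grid.n_cols)
        pop = cfg.community_pop_median * math.exp(
            rng.normal(0.0, cfg.community_pop_sigma_log)
        )
        # geometric-mean-one rescaling of the population term
        pop_term = pop / cfg.community_pop_median
        base_pollen = float(pollen_surface.values[i, j])
        for year in cfg.years:
            pollen = base_pollen * math.exp(rng.normal(0.0, 0.1))  # mild year-to-year wobble
            eps = math.exp(rng.normal(0.0, cfg.noise_sigma_log))
            expected = cfg.community_scale * pollen**cfg.true_elasticity * pop_term * eps
            patients = min(int(round(expected)), int(pop))
            records.append(
                CommunityRecord(
                    community_id=f"community_{c:03d}",
                    x=float(xs[i, j]),
                    y=float(ys[i, j]),
                    year=year,
                    patients=max(0, patients),
                    pollen_integral=pollen,
                    population=int(pop),
                )
            )
    return records


# ---------------------------------------------------------------------------
# Daily temperatures and beetle cohorts
# ---------------------------------------------------------------------------

DEFAULT_SITE_ALTITUDES = {  # m a.s.l., the altitudinal-gradient design
    "alt_0130": 130.0,
    "alt_0250": 250.0,
    "alt_0480": 480.0,
    "alt_0700": 700.0,
    "alt_1230": 1230.0,
}


def gen_daily_temps(
    cfg: SyntheticConfig,
    site_altitudes: dict[str, float] | None = None,
    year: int = 2016,
) -> dict[str, DailyTemperatureSeries]:
    """Sinusoidal annual temperatures with an altitudinal lapse and daily noise."""
    rng = _rng(cfg.seed, "temps")
    site_altitudes = site_altitudes or DEFAULT_SITE_ALTITUDES
    start = dt.date(year, 1, 1)
    n_days = (dt.date(year, 12, 31) - start).days + 1
    doy = np.arange(n_days)
    out: dict[str, DailyTemperatureSeries] = {}
    for site, alt in site_altitudes.items():
        mean = (
            cfg.temp_mean
            + cfg.temp_amplitude * np.sin(2 * np.pi * (doy - 105) / 365.25)
            + cfg.lapse_rate * alt / 1000.0
            + rng.normal(0.0, cfg.temp_noise_sigma, size=n_days)
        )
        half = cfg.diurnal_range / 2.0
        out[site] = DailyTemperatureSeries(
            site,
            [start + dt.timedelta(days=int(d)) for d in doy],
            mean - half,
            mean + half,
        )
    return out


def gen_cohorts(
    cfg: SyntheticConfig,
    series_by_site: dict[str, DailyTemperatureSeries],
    ovipositions: Sequence[tuple[str, dt.date]] | None = None,
) -> list[CohortRecord]:
    """Cohorts whose emergence date is set by the true GDD-per-generation.

    For each oviposition, adult emergence is the day whose accumulated GDD
    (simple-average method above the true base) is closest to the true
    per-generation requirement; day-level discretisation is the only error.
    """
    if ovipositions is None:
        ovipositions = []
        for site in series_by_site:
            year = series_by_site[site].dates[0].year
            ovipositions.append((site, dt.date(year, 7, 1)))
            ovipositions.append((site, dt.date(year, 8, 9)))
    target = cfg.voltinism.gdd_per_generation
    base = cfg.voltinism.base_temp
    cohorts = []
    for site, ovi in ovipositions:
        series = series_by_site[site]
        dates = np.array(series.dates)
        sel = dates >= ovi
        mean_t = (series.t_min[sel] + series.t_max[sel]) / 2.0
        cum = np.cumsum(np.maximum(0.0, mean_t - base))
        if cum[-1] < target:
            continue  # site too cold for this cohort to complete
        k = int(np.argmin(np.abs(cum - target)))
        emergence = dates[sel][k]
        if emergence <= ovi:
            continue
        cohorts.append(CohortRecord(site, ovi, emergence))
    return cohorts


# ---------------------------------------------------------------------------
# Field plots
# ---------------------------------------------------------------------------

DEFAULT_PLOT_SITES = ("CO", "GR", "MA")  # CO has no exclusion treatment


def gen_plot_data(
    cfg: SyntheticConfig, year: int = 2015
) -> tuple[pd.DataFrame, list[AllometrySample]]:
    """Plot table (with hurdle-true densities) + per-site-treatment allometry.

    Densities are drawn from the hurdle truth directly: production is
    Bernoulli with a site effect on the logit scale, positive density is
    Poisson with a site effect on the log scale.  Plant counts, maturation
    fractions and volumes are plausible covariates for I/O round-trips but
    carry no additional signal.
    """
    rng = _rng(cfg.seed, "plots")
    site_u = {s: rng.normal(0.0, cfg.site_sigma_logit) for s in DEFAULT_PLOT_SITES}
    site_w = {s: rng.normal(0.0, cfg.site_sigma_log) for s in DEFAULT_PLOT_SITES}
    rows = []
    for site in DEFAULT_PLOT_SITES:
        treatments = [Treatment.CONTROL]
        if site != "CO":
            treatments.append(Treatment.BEETLE_EXCLUDED)
        for tr in treatments:
            p = cfg.p_control if tr is Treatment.CONTROL else cfg.p_excluded
            mu = cfg.mu_control if tr is Treatment.CONTROL else cfg.mu_excluded
            if p <= 0.0 or p >= 1.0:  # degenerate truth: site effect cannot move it
                p_site = p
            else:
                p_site = 1.0 / (1.0 + math.exp(-(math.log(p / (1 - p)) + site_u[site])))
            mu_site = mu * math.exp(site_w[site])
            for k in range(cfg.plots_per_site_treatment):
                produced = rng.random() < p_site
                density = float(rng.poisson(mu_site)) if produced else 0.0
                n_plants = int(rng.integers(5, 60))
                rows.append(
                    {
                        "plot": f"{site}_{tr.value}_{k:02d}",
                        "site": site,
                        "treatment": tr.value,
                        "year": year,
                        "n_plants": n_plants,
                        "frac_matured": round(rng.uniform(0.2, 0.9), 3) if produced else 0.0,
                        "mean_log_volume": round(rng.normal(6.0, 0.8), 4) if produced else np.nan,
                        "excluded": False,
                        "density": density,
                    }
                )
    plots = pd.DataFrame(rows)

    allometry = []
    for site in DEFAULT_PLOT_SITES:
        for tr in (Treatment.CONTROL, Treatment.BEETLE_EXCLUDED):
            if site == "CO" and tr is Treatment.BEETLE_EXCLUDED:
                continue
            log_vol = rng.normal(6.0, 0.8, size=21)
            log_rac = (
                cfg.allometry_alpha
                + cfg.allometry_beta * log_vol
                + rng.normal(0.0, cfg.allometry_sigma, size=21)
            )
            allometry.append(AllometrySample(site, tr, log_vol, log_rac))
    return plots, allometry


# ---------------------------------------------------------------------------
# Pre/post daily pollen (Milan-like)
# ---------------------------------------------------------------------------

def gen_prepost_pollen(cfg: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Daily station series before/after beetle arrival with a known reduction.

    The pre-arrival season is a Gaussian pulse scaled so the across-station
    mean daily integral equals ``pre_target_mean``; the post series is the
    same shape damped by a level-dependent reduction that starts at
    ``reduction_early`` and tapers to ``reduction_late`` as the cumulative
    pre-arrival level grows.
    """
    rng = _rng(cfg.seed, "prepost")
    season_start = dt.date(2008, 7, 7)
    n_days = 107  # July 7 - Oct 21
    days = np.arange(n_days)
    shape = np.exp(-((days - 45) ** 2) / (2 * 18.0**2))
    shape *= cfg.pre_target_mean / shape.mean()

    cum = np.cumsum(shape)
    taper = np.exp(-cum / (0.3 * cum[-1]))
    reduction = cfg.reduction_late + (cfg.reduction_early - cfg.reduction_late) * taper
    post_shape = shape * (1.0 - reduction)
    if cfg.post_target_mean is not None:
        post_shape = post_shape * (cfg.post_target_mean / post_shape.mean())

    def series(base: np.ndarray, year: int) -> pd.DataFrame:
        start = dt.date(year, season_start.month, season_start.day)
        rows = []
        for s in range(cfg.prepost_stations):
            noise = np.exp(rng.normal(0.0, cfg.prepost_noise_sigma_log, size=n_days))
            for d in range(n_days):
                rows.append(
                    {
                        "station": f"milan_{s}",
                        "date": start + dt.timedelta(days=int(d)),
                        "concentration": float(base[d] * noise[d]),
                    }
                )
        return pd.DataFrame(rows)

    return series(shape, 2008), series(post_shape, 2016)


# ---------------------------------------------------------------------------
# Suitability masks and thermal (GDD) field
# ---------------------------------------------------------------------------

def gen_generations_inputs(
    cfg: SyntheticConfig,
) -> RasterGrid:
    """Seasonal-GDD surface: a north-south thermal gradient plus noise."""
    rng = _rng(cfg.seed, "gdd")
    xs, ys = cfg.grid.cell_centres()
    v = (cfg.grid.origin_y - ys) / (cfg.grid.n_rows * cfg.grid.cell_size)  # 0 north, 1 south
    gdd = 150.0 + 1400.0 * v + rng.normal(0.0, 60.0, size=cfg.grid.shape)
    return RasterGrid(cfg.grid, np.clip(gdd, 0.0, None))


def gen_suitability_masks(
    cfg: SyntheticConfig, gdd: RasterGrid
) -> tuple[RasterGrid, dict[str, RasterGrid]]:
    """Host-plant mask and nested lower/mean/upper beetle suitability masks.

    Suitability tracks the thermal field but is not a pure function of it
    (real suitability maps also reflect precipitation and seasonality), so
    a bioclimatic score adds noise to the degree-day surface before
    thresholding.  The lower mask is a subset of the mean mask, the upper
    a superset (nesting mirrors the way confidence maps bound a central
    suitability estimate).
    """
    rng = _rng(cfg.seed, "suitability")
    g1 = cfg.voltinism.gdd_per_generation
    score = gdd.values + rng.normal(0.0, 0.5 * g1, size=cfg.grid.shape)
    plant = RasterGrid(cfg.grid, (score > 0.3 * g1).astype(float))
    beetle = {
        "lower": RasterGrid(cfg.grid, (score > 1.6 * g1).astype(float)),
        "mean": RasterGrid(cfg.grid, (score > 1.0 * g1).astype(float)),
        "upper": RasterGrid(cfg.grid, (score > 0.6 * g1).astype(float)),
    }
    return plant, beetle
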