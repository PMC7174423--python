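# Methods

This note records the modelling assumptions, numerical choices and known
limitations behind each stage of the pipeline.  It documents *how* the
package computes; every number quoted here is produced by the test suite
or the scripts, not asserted from memory.

## Spatial interpolation

Station observations are brought onto a regular planar lattice (default
10 km cells, row 0 northernmost, values registered at cell centres) by
inverse-distance weighting with power 2 over the 12 nearest stations, both
configurable.  IDW was chosen because it is deterministic, has no free
statistical parameters to fit, and is exact at station locations (a cell
whose centre lies within cell_size/1000 of a station takes the station
value).  No interpolation method is claimed to be canonical for this
problem; kriging is deliberately out of scope.  Coordinates are assumed
already projected to metres; the CRS string is carried as opaque metadata
and never enters the arithmetic.  Cells outside the convex hull of the
stations are extrapolated by the same nearest-k rule.  IDW output is a
convex combination of station values, so interpolated rates cannot leave
[0, 1]; the product map is clamped anyway to guard degenerate configs.

Jenks natural breaks are computed by exact dynamic programming on the
sorted values (O(n²k) with prefix sums), minimising total within-class sum
of squared deviations.  Ties are broken towards the smaller left class so
the partition is deterministic; the exhaustive-enumeration oracle in the
test suite confirms optimality for n ≤ 12, k ≤ 4.

Raster I/O uses a self-describing gridded-CSV dialect (`#origin_x=…`
headers, `NA` for nodata).  Nodata propagates through all raster
arithmetic and masked cells are excluded from every reduction.

## Sensitisation and patient mapping

The two study layers (overall sensitisation; ragweed sensitisation among
sensitised persons) are interpolated independently and multiplied
cellwise.  Studies are unweighted by sample size in the interpolation —
the sample size is retained only so the synthetic generator can apply
binomial noise.  The clinical-relevance correction is a per-country scalar
multiply; each cell belongs to exactly one country via the country raster,
with no area-sharing at borders.  The exposure exclusion is strict:
cells with seasonal pollen integral < 10 grains/m³ contribute zero
patients (zero, not nodata — they remain part of the study area).  At
every stage 0 ≤ patients ≤ population cellwise.

## Exposure–response elasticity

Community records are averaged over the requested year range (communities
missing years contribute their available years; communities with no
record drop out), then the model `ln(patients) = β ln(pollen)` is fitted
by closed-form least squares without a constant:

    β̂ = Σ ln xᵢ ln yᵢ / Σ (ln xᵢ)²,   se² = s² / Σ (ln xᵢ)²,

with s² the residual mean square on n − 1 degrees of freedom and an
uncentred R².  The fit is on community means (one point per community),
not the community-year panel, and is unweighted by population.  Pairs
with non-positive pollen or patients are excluded (no pseudo-counts; the
model is undefined there) and the exclusion count is reported.

Two caveats are intentional features of this model and are surfaced by
the tests rather than hidden: (a) the no-intercept fit is sensitive to
units — multiplying all patient counts by c shifts β̂ by exactly
`ln c · Σln x / Σ(ln x)²`; (b) averaging multiplicative noise before
taking logs adds a small positive offset (ln of an averaged lognormal
exceeds its median), which at the default noise level biases β̂ upward by
roughly half a standard error.  Projections therefore expose both the
first-order reading `Δ% = β · Δpollen%` and the power-law form
`(1 − r)^β`, which is consistent with the fitted model for large
reductions; the pipeline defaults to the power law.

## Economics

Per-patient annual cost is `round_half_up(median_treatment_cost × (1 +
work_loss_ratio))`, €670 at the defaults (565, 0.185); rounding applies
to the per-patient figure only, aggregates stay unrounded.  The median is
computed at run time from the country/treatment cost table (the packaged
table is a synthetic nine-row stand-in spanning €8.30–€8060 with median
565).  Country costs are weighted by PPP-adjusted health expenditure per
capita, normalised by the patient-weighted mean weight, so uniform
weights (or a single country) reproduce `patients × cost` exactly and a
common rescaling of all weights changes nothing; a named reference
country can be selected instead.  The work-loss ratio is applied
uniformly across countries.

## Beetle phenology and pollen reduction

Degree days accumulate by the simple daily-average method,
`max(0, (t_min + t_max)/2 − 13.3)` per day — the standard entomological
choice for coarse daily data; a single-sine accumulator could be slotted
in behind the same interface.  One generation is 288.7 GDD (field
estimate; the cohort estimator averages per-cohort accumulation from
oviposition to adult emergence, unweighted).  Completed generations are
`⌊GDD/288.7⌋`; the seasonal accumulation window defaults to the calendar
window of the supplied series and is configurable.  Overwintering and
diapause timing are not modelled.

The generation-dependent reduction policy maps ≥ 3 generations → 0.86,
1–2 → 0.30, 0 or unsuitable → 0, applied only inside the intersection of
the beetle and host-plant suitability masks.  The suitability masks are
*inputs* (binary rasters); fitting the bioclimatic distribution models
that produce them is out of scope.  The pre/post station comparison
reports period means per station, averages across stations and the drop
`1 − post/pre`; the empirical reduction curve orders days within the
season, cumulates the pre-arrival profile to define the level axis and
reports `1 − cum_post/cum_pre` at each level.  The sentence-level
ambiguity in how such a curve can be built is isolated behind this one
operation so an alternative reading can be swapped in.

## Field experiment and hurdle model

Per-plot raceme density is `n·m·exp(vβ+α)` divided by plot area, with
(α, β) the site-treatment OLS of log raceme length on log plant volume
and the site-treatment mean volume substituted when a plot has no
measured plants.  Plot exclusions (no plants in the establishment year,
grass-dominated block) are row flags on the input, not hard-coded names;
when a year lacks mature plants for allometry the previous year's
site-treatment fit is the designated fallback.

The hurdle analysis fits two GLMMs with a Gaussian site random intercept:
Bernoulli-logit on `density > 0` over all plots, Poisson-log on the
positive densities rounded half-up to integer cm/m² (the closest faithful
likelihood for a Poisson fit to continuous estimated lengths;
overdispersion is reported, not modelled).  The random intercept is
integrated by the Laplace approximation — with one grouping factor the
marginal likelihood factorises and each group mode is a damped 1-D Newton
solve; the outer optimisation is Nelder–Mead over (fixed effects, log σ).
As σ → 0 the marginal collapses exactly to the plain GLM likelihood,
which the tests exploit as an independent oracle (statsmodels GLM,
agreement ≤ 1e-6).  When the variance MLE is at zero, fixed-effect
standard errors come from the plain-GLM information conditional on σ = 0.
Complete separation is detected by a bound on the linear predictor and
reported as a boundary fit with suppressed standard errors, never a
crash; the degenerate all-produce (or none-produce) binomial part — the
pattern seen in a year where every exclusion plot and no control plot
produced racemes — is flagged and contributes 100 % to the multi-year
reduction average.  Treatment-level values are reported on the response
scale at random effect 0, the unconditional expectation is
`p(produce) × E[density | > 0]`, and the percent production reduction is
`100(1 − E[control]/E[excluded])`, averaged across years when several are
supplied (the aggregation is configurable by passing per-year values).

## Synthetic data

All generators are pure functions of (config, seed); each draws from its
own stream derived from the master seed by a fixed offset, so adding a
generator never perturbs the others.  What they emulate, and what they
deliberately do not:

- **Pollen surface**: sum of Gaussian hot-spots (3 by default, amplitudes
  800–4000 grains/m³) on a low background (20 grains/m³), stations read
  the surface with lognormal noise (σ = 0.2).  No dispersal physics, no
  coastline.
- **Sensitisation studies**: binomial draws of smooth truth fields at 50
  and 80 random locations (the two layers' study counts), 150–2000
  persons tested.
- **Community panel**: 313 communities × 9 years with
  `patients = pollen^0.84 × (pop/median) × ε`, `ln ε ~ N(0, 0.3²)`,
  patients rounded and capped at population.  The non-pollen multiplier
  has geometric mean one by construction, which is exactly the condition
  under which the through-origin fit is unbiased; real reimbursement data
  offer no such guarantee.
- **Temperatures**: sinusoidal annual cycle (mean 14 °C, amplitude 9 °C)
  with a −6.5 °C/km lapse over the five-site altitudinal ladder
  (130–1230 m), daily Gaussian noise, fixed diurnal range.  Cohort
  emergence dates are set where cumulative GDD is closest to 288.7, so
  day-level discretisation is the only recovery error; sites too cold to
  complete a generation drop their cohorts, as in the field.
- **Field plots**: three sites, 14 plots per site-treatment, one site
  without the exclusion treatment (70 plots); production is Bernoulli and
  positive density Poisson around the truth {0.26, 0.84, 260, 905} with
  modest site effects (logit σ 0.3, log σ 0.1).  Plant counts and volumes
  in the table are plausible covariates for I/O round-trips and carry no
  extra signal.
- **Pre/post pollen**: three stations, 107-day season, Gaussian pulse
  scaled to a 46.2 grains/m³ pre-arrival mean, damped by a reduction that
  starts at 0.90 and tapers to 0.837 with cumulative level; an optional
  post-period target mean (7.5) rescales the damped series.
- **Countries/population**: Voronoi cells of random capitals and a
  lognormal population field with city bumps — the simplest structures
  with the heterogeneity the PPP weighting and country masking need.

Passing tests on these data demonstrate correctness of the estimators
under the stated generating models, not the realism of any European map.

## Problem sizes and determinism

The shipped analyses use a 20 × 25 cell grid, 100 stations, 130 studies,
313 communities × 9 years, 70 plots × 100 replicates for the hurdle
recovery study and 500 replicates for the likelihood-ratio calibration —
sizes chosen so each stage's statistical behaviour is measurable while a
full run of the suite stays in the low minutes.  Every random draw
descends from an explicit seed; reruns are bit-identical, and the CLI
records config hashes and package versions in its provenance blocks.

## Known limitations

- The interpolation method, search radius and sea-cell handling of the
  original exposure maps are not public; here they are configuration, and
  no claim is made that the defaults reproduce those maps.
- Scenario bounds come from the lower/mean/upper suitability masks only;
  they are not sampling confidence intervals and do not propagate
  elasticity or cost uncertainty.
- Whether cells that fall below the 10 grains/m³ threshold after the
  beetle reduction should stop contributing patients is a modelling
  choice (on by default, switchable) consistent with the baseline
  exclusion rule.
- The Poisson positive part ignores overdispersion; confidence intervals
  for the positive means are accordingly narrow.
- No age structure, temporal sensitisation trends, other allergens
  (*Artemisia*), seed production or insecticide side effects.
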