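# Methods

This note documents the statistical machinery in `heatfe`: the estimators,
their numerical realisation, the conventions and defaults, what the
synthetic data generator does and does not emulate, and the design choices
made where more than one defensible option existed.

## 1. The fixed-effects estimator (`panel_core`)

The model is a weighted linear regression of the monthly death rate on an
exposure basis and controls, with two absorbed fixed-effect dimensions:
county-month cells δ_im (county-specific seasonality, local time-invariant
factors) and state-year cells α_st (state-level annual trends and shocks).
Weights are county populations; inference clusters by county.

**Demeaning.** The fixed effects are absorbed by alternating projections:
Gauss–Seidel sweeps that subtract weighted group means over each FE
dimension in turn, applied jointly to the response and all regressors. A
sweep terminates when the largest absolute adjustment applied to any cell
falls below `tol × scale`, with `tol = 1e-10` and `scale` the largest
absolute value of the input data. Convergence failure raises, reporting the
last adjustment. On the resulting within-transformed data, slopes are
solved by QR least squares on the √w-scaled design. Correctness is defined
by equivalence with the dense dummy-variable WLS solution, which the test
suite enforces at 1e-8 relative tolerance on randomized panels.

**Rank handling.** A regressor absorbed by the fixed effects (constant
within cells) is detected by comparing its demeaned norm with its
pre-demeaning norm; a linear combination among surviving regressors is
detected by a rank test on the normalized demeaned design. Both raise a
`CollinearityError` naming the offending column — silently dropping or
zeroing a coefficient would corrupt downstream curve and net-effect
arithmetic. Singleton FE cells are retained (they demean to zero) with a
logged count.

**Cluster-robust covariance.** The CR1 sandwich sums weighted score vectors
within clusters: S_g = Σ_{i∈g} w_i x_i e_i, meat = Σ_g S_g S_g′, with
small-sample factor G/(G−1) · (N−1)/(N−K). K counts the slope terms plus
the absorbed fixed-effect degrees of freedom, computed exactly as
G₁ + G₂ − (number of connected components of the bipartite county-month ×
state-year graph), by union-find. With every observation its own cluster
the estimator reduces exactly to HC1, which is cross-checked against
statsmodels in the tests. A single cluster raises (the variance is
unidentified).

**AIC.** Model comparison uses the Gaussian form n·log(SSR_w/n) + 2k with
k the number of slope parameters only. Absorbed FE degrees of freedom are
identical across the candidate bases compared on a given panel, so they
shift every candidate's AIC equally and are omitted. The value is
meaningful only for comparing fits on the same panel under the same FE
structure; rescaling the response by c shifts all AICs uniformly by
n·log(c²). A perfect fit (zero SSR, possible only on noiseless synthetic
input) yields AIC = −∞ with a logged warning rather than an error, so that
noiseless closed-form checks can still inspect coefficients.

## 2. Exposure-response bases and the anchored curve (`exposure_response`)

Candidate shapes for f(temp):

| kind | parameters | columns |
|---|---|---|
| `linear` | — | 1 |
| `ncs3` | natural cubic spline, knots 0/10/20 °C | 2 |
| `ncs7` | natural cubic spline, 7 knots evenly on [−17, 33] °C | 6 |
| `polynomial` | raw powers, default degree 3 | degree |
| `bspline` | cubic, interior knots 0/10/20 °C, boundary at sample range | interior+2 |

Natural splines use the textbook naturalized truncated-power basis: with
knots x₁<…<x_K the columns are x and d_k(x) − d_{K−1}(x),
d_k(x) = [(x−x_k)₊³ − (x−x_K)₊³]/(x_K − x_k). This spans exactly the
natural cubic splines on those knots — linear beyond the boundary knots
(zero second derivative outside), giving linear extrapolation by
construction — and yields K−1 columns once the intercept is absorbed by
the fixed effects. All three stated knots are treated as interior knots of
the natural spline; no additional boundary knots are introduced. Any
full-rank reparameterisation would produce the same fitted curve; the
curve, not the coefficients, is the contract. The B-spline candidate drops
one column of its partition of unity (collinear with the absorbed
intercept).

Model selection fits every candidate under identical FE, weights and
clustering, and returns the AIC argmin; ties (within 1e-9) break toward
fewer parameters, then listing order. Candidates that fail to fit are
recorded and excluded with a warning rather than aborting the comparison.

The response curve is reported relative to the expected rate at a
reference temperature (10 °C by default): effect(T) = b(T)′γ̂ − b(ref)′γ̂,
with pointwise variance (b(T)−b(ref))′ V (b(T)−b(ref)) from the
cluster-robust covariance and 95 % bounds at ±1.96·SE. Grid points outside
the observed temperature range are flagged as extrapolation, not dropped.
The curve table carries the sample-temperature frequency per grid bin, the
histogram convention used when plotting exposure-response figures.

## 3. Displacement (`displacement`)

Lag L of an exposure for row (county, m) is that county's value at
calendar month m−L; L = 1 is the previous month, L = −1 the next. Shifts
never cross county boundaries, and a gap in a county's month sequence is
an error — shifting across an unnoticed gap would silently mislabel
exposures. Rows whose requested lags fall outside the panel are dropped
from estimation with a logged count; by default each lag specification
uses its own complete-case sample (fitting nested specifications on a
common sample is available by pre-filtering with the widest window).

The net (overall) effect is γ̂₀ + γ̂₁ — current plus previous month — with
SE = √(V₀₀ + V₁₁ + 2V₀₁) from the joint cluster-robust covariance. The
±2-month window serves as the robustness check that the one-month window
captures the full displacement.

## 4. Heterogeneity (`heterogeneity`)

Three designs, all under the standard FE/weights/clustering:

* **Interaction**: temp, temp×D, precip, precip×D, with D a 0/1 indicator.
  D's main effect is intentionally absent — for the county-attribute
  indicators used here it is absorbed by the county-month fixed effects.
  "Above/below average" indicators are defined against the
  population-weighted sample mean of the moderating variable. The group
  slopes are γ₁ (D=0) and γ₁+γ₂ (D=1), the latter with a delta-method SE.
  A constant indicator raises immediately; an indicator whose interaction
  becomes collinear after demeaning raises through the rank check rather
  than returning a silent zero. Note that when D is defined by
  thresholding the exposure itself (e.g. temp > 20 °C), the interacted
  model without a main D term is a misspecification of a kinked truth and
  γ₂ underestimates the slope difference while preserving its sign and
  significance; the binned fits are the unbiased view in that case.
* **Binned**: the panel is subset by bins of one variable and the linear
  model is refit independently per bin. Temperature and precipitation bins
  are assigned per row; population bins per county (time-invariant), so a
  county never straddles bins. Empty bins are reported with n = 0; bins
  with fewer than two county clusters are reported but not estimated.
* **Categorical**: temp and precip fully interacted with category dummies
  (year, state, month, climate region — the region label is an input
  column). The reported per-category slope is the base slope plus the
  category's interaction with delta-method SE; the reference category
  (first in sorted order) is marked in its label. Categories with a single
  county cluster are estimated but flagged.

Subgroup tables carry estimate, SE, two-sided normal p-value, 95 % CI
(±1.96·SE throughout the package) and an α = 0.05 significance flag. Since
the absolute rate scale is a convention (see §6), tables optionally report
each effect both in raw rate units and as a percent of the
population-weighted mean death rate, labeled as such.

## 5. Projection (`projection`)

Grid-cell warming is aggregated to counties by overlap-weighted means
(weights renormalized per county; zero-overlap counties raise). Each
model's county ΔT is the future-minus-baseline period difference; within
the projection horizon the path from 0 at the base year to ΔT at the end
year defaults to a **linear ramp**, with a `step` alternative — only the
end-of-horizon difference is identified by the inputs, so the within-
horizon path is an explicit modelling choice, and cumulative totals are
roughly halved under `linear` relative to `step`.

Excess deaths per county-year are pop_ct · ΔT_ct · (β/rate_scale) ·
`months_per_year_factor`. β is a *monthly* rate coefficient while ΔT is an
annual mean warming, so the per-year excess multiplies by 12 by default;
the factor is exposed in the configuration because this annualisation is
an assumption, not an identity. β is the net (current + previous month)
displacement-adjusted effect.

Uncertainty: a county-level cluster bootstrap resamples counties with
replacement (keeping each resampled county's full time series under a
fresh id, so duplicated draws act as distinct clusters and FE cells),
refits the displacement model, and records the net β. B bootstrap draws ×
M climate models give exactly B·M cumulative trajectories, summarised by
the median, interquartile range and 2.5/97.5 percentiles per year. A
failed refit is redrawn with a capped retry count and a logged tally. The
production-scale configuration (B = 1,000, M = 30, i.e. 30,000
trajectories) is a parameter choice; tests and the acceptance script run
B = 200, M = 10, which already stabilises the reported quantiles to within
a few percent.

## 6. Synthetic data (`synthetic_data`)

The generator emulates the structure the estimator assumes:

* Balanced county-month panels; counties assigned round-robin to states.
* Temperature: county base levels uniform on [2, 18] °C, a sinusoidal
  seasonal cycle peaking in July (amplitude 10 °C), and iid year-to-year
  noise (sd 2 °C). Because the deterministic seasonal part is constant
  within county-month cells, only this noise identifies the within
  estimator — mirroring the real identification story.
* Precipitation: truncated normal, mean 80 mm, sd 40 mm, linear effect
  −0.02 per mm.
* Fixed effects: county-month intercepts (sd 5) and state-year intercepts
  (sd 2). With `confounded=True`, county-month intercepts are drawn with
  correlation ρ = 0.5 to the cell's deterministic mean temperature, which
  biases pooled OLS while leaving the within estimator consistent — the
  contrast the tests rely on.
* Outcome: by default a continuous rate (the estimator is linear in the
  rate); an optional Poisson mode draws deaths ~ Poisson(rate·pop) for
  realism. Rates are expressed as deaths per 10⁷ person-months, a scale on
  which realistic effects are order one; the absolute scale is a package
  convention, exposed as configuration, since percent-style effect tables
  depend on the mean rate rather than the scale.
* Truth shapes: linear (β per °C), natural-cubic (`SplineResponse`, values
  at knots, linear beyond), and two-regime piecewise linear
  (`PiecewiseResponse`) for heterogeneity recovery; lagged effects are
  applied against an extended temperature axis so that lag/lead columns
  never fall off the panel edge.
* Default study size: 100 counties, 10 states, 10 years (12,000 rows).
  Model-selection experiments use 420 counties (50,400 rows) so that the
  spline curvature is well identified.

What the generator does **not** emulate: spatial correlation of weather
beyond the common seasonal shape (station-network tests use constant and
planar fields only), serial correlation of errors within counties,
outcome integer sparseness at realistic death counts (unless Poisson mode
is enabled), migration or demographic drift, and any real US geography.
Passing tests therefore demonstrate the estimators' correctness and
calibration under the assumed error structure — they do not validate
substantive conclusions about real police-violence data.

## 7. Spatial interpolation (`spatial_interp`)

Station-to-centroid interpolation is inverse-distance weighting with
great-circle (haversine) distances — at CONUS scale plane geometry would
distort distances materially. Weights are d^(−power), default power 2,
over the k nearest stations (default: all). A station coincident with the
target returns that station's value exactly; coincident stations with
conflicting values raise, naming the offenders. The interpolant is a convex
combination of station values and is invariant to uniform distance
rescaling. Daily interpolated values are aggregated within calendar months:
temperature by the mean; precipitation by the mean as well, for symmetry —
with a documented `sum` option since monthly precipitation totals are the
more common convention. Months with no daily records are absent, never
zero-filled; counties with no reachable station appear in an exclusion
report rather than being dropped silently.

## 8. Validation and the pipeline (`io_cli`)

`validate_panel` enforces the panel contract — required columns, one row
per (county, year, month), positive population, finite weather, a death
rate consistent with deaths/population when both are present — excluding
and counting failing rows per rule; nothing is imputed. County and state
identifiers are opaque strings, so real FIPS codes pass through untouched.

`run_pipeline` chains simulate/load → validate → AIC basis selection →
displacement fit and net effect → response curve → heterogeneity tables →
projection, writing every table as CSV (full-precision floats;
`read_table` restores them exactly), a JSON manifest (seed, config hash,
package versions) sufficient to reproduce the run bit for bit, and a
stage-prefixed log. Any stage failure aborts with the stage name while
retaining completed artifacts. The `heatfe` CLI exposes each stage as a
subcommand; exit codes are 0 (success), 2 (validation failure),
3 (estimation failure).

## 9. Known limitations

* AIC with a 2-point penalty retains a ≈16 % asymptotic probability of
  preferring a model with one spurious extra parameter (P(χ²₁ > 2)), and
  population weighting inflates this further; model selection between
  nested bases should therefore be read as descriptive, not as a test
  with controlled size.
* The interaction model inherits the exposure-threshold caveat of §4.
* The projection treats β as constant over the horizon (no adaptation)
  and the ΔT path as deterministic per model; only β-sampling and
  between-model spread enter the uncertainty band.
* Two-way clustering, instrumental variables and distributed-lag
  nonlinear (smooth lag surface) models are out of scope.
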