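# Methods

## Flight models and their assumptions

Both flight models treat a propagule released at height *h_r* as falling at
its terminal velocity *V_t* from the instant of release while being advected
horizontally at the local wind speed. The assumptions inherited from the
ballistic tradition are: instantaneous deceleration to *V_t* (empirically
justified for these mericarps — drop experiments show no dependence of the
measured fall speed on release heights between 0.8 and 4.3 m), horizontal
propagule speed equal to wind speed, no turbulence, flat open terrain with
no obstacles. Turbulence matters mainly for propagules with *V_t* below
~0.3 m/s; hogweed mericarps fall at 0.9–2.3 m/s, so it is neglected.

The ballistic model uses a height-independent wind: *D = h_r·u/V_t*. The
gradient model replaces *u* with the Hellmann profile
*v(z) = v_hr·(z/h_r)^α* evaluated along the fall. With the propagule height
*h(t) = V_t·(t_f − t)* and *t_f = h_r/V_t*, the experienced wind is
*v(t) = v_hr·((t_f − t)/t_f)^α*, and integrating over *t ∈ [0, t_f]* gives
the closed form *D = h_r·v_hr/(V_t·(1+α))*. The integral is interpreted
over time (consistent with the height-vs-time substitution that produces
it); the analytic antiderivative is the primary code path and adaptive
quadrature of *v(t)* serves as the test oracle (relative agreement ≤ 1e−9
over the full parameter box α ∈ [0,1], h_r ∈ (0.1,5], V_t ∈ (0.1,5],
v_hr ∈ [0,30]).

Zero wind is a valid input returning 0 m (zero-wind launches occur in the
field data), not an error. All internal computation is SI (m, s, m/s); unit
conversion happens only at declared boundaries (mg → g inside wing loading).

## Parameters

| parameter | meaning | unit | default | why |
|---|---|---|---|---|
| α | Hellmann exponent (roughness/stability) | – | 0.29 | calibrated against launch experiments; every API accepts it explicitly |
| *V_t* | propagule terminal velocity | m/s | 1.62 natural / 1.72 artificial | group medians from drop experiments |
| *h_r* | release height | m | 3.0 (launches), 3.85 (LDD maximum) | launch-device height is a config value; 3.85 m is the tallest recorded umbel |
| spread slope, intercept | *D_sd = 0.35·v + 0.51* | m per (m/s), m | 0.35, 0.51 | empirical within-batch scatter fit (9 wind classes) |
| critical wind | minimum gust that detaches a propagule | m/s | Uniform(0, 15) | observed release from near-zero gusts up to propagules surviving >15 m/s; no distribution is published, so a maximally non-committal uniform span is used, fully configurable |

## Calibration

`AlphaCalibration` regresses the empirical per-launch **mean** distance on
the gradient-model prediction driven by the launch's **maximum** wind
(empirically the best-correlated pairing), by OLS **with intercept**, for
each α on the 0.05–0.50 grid (step 0.01); the optimum minimises
|slope − 1|, ties broken toward smaller α (smoother profile). The
regression direction matters (swapping axes inverts slopes): empirical is
the response, modelled the regressor, matching how the fitted slope is
reported on the mean-distance axis. Because the modelled distances scale as
1/(1+α), the slope profile is strictly increasing in α, so the grid minimum
is unique up to resolution.

Diagnostics at the optimum: Pearson r between empirical and modelled means,
and a two-sample Kolmogorov–Smirnov test comparing the pooled per-propagule
empirical distances against the modelled launch values repeated once per
propagule (launch-mean-level KS would be the alternative; the pooled choice
uses all measurements and is documented rather than claimed canonical).

The spread regression bins all distances into left-closed 1 m/s classes of
the launch's maximum wind, drops classes with fewer than 2 distances (sd
undefined), requires ≥ 3 classes, and regresses the per-class sd on the
class mean wind.

**Precision of the α estimate.** On noiseless self-generated data the
calibration recovers the generating α exactly (grid-limited). Under the
spread-model noise at the study design (37 launches of 8–20 propagules,
winds 0–9 m/s), repeated-seed simulation (see `scripts/acceptance.py`,
`alpha_recovery_rate_within_0p03`) shows the estimator is unbiased with a
sampling spread of roughly ±0.04 (1 sd): single experiments of this size
localise α to about the second decimal place, not beyond. This is a
property of the slope-matching estimator at this noise level, since the α
uncertainty is (1+α) times the fitted-slope uncertainty.

## Stochastic kernel

The individual-based simulator computes each propagule separately:

1. draw *V_t* and *h_r* (fixed scalars, or resampled with replacement from
   supplied empirical tables) and a critical wind speed;
2. the propagule releases at the first wind record whose **gust** reaches
   its critical wind (first-crossing scan; never released → counted, not
   flown). The gust, not the period mean, drives both release and flight,
   consistent with maximum wind being the best distance predictor;
3. the gust is corrected from anemometer height to *h_r* via the Hellmann
   profile and flown with the gradient model;
4. optional zero-mean Gaussian noise with sd from the spread model. The
   spread model gives only an sd, not a family; Gaussian noise is adopted,
   with negative landing distances resampled by default (keeps the mean at
   the deterministic value when truncation is rare) or floored at zero via
   `noise_mode="floor"`.

Seeded generators are mandatory (`KernelConfig.seed`); there is no hidden
global randomness, and one seed reproduces the kernel bit for bit.
Post-landing transport (e.g. dragging over snow or ice crust) is out of
scope, as are 2-D spread maps and population dynamics.

The station LDD workflow (`max_dispersal_estimate`) reproduces the
reporting convention of the headline estimates: the corrected wind is
rounded to the nearest integer m/s *before* the distance computation, and
distance and sd are rounded to the nearest metre — in the reporting layer
only, never in the core math. With the 23 m/s station maximum the closed
form gives 55.75 m (rounds to 56); the corresponding printed estimate is
55 m, so a ±1 m discrepancy on that one value is inherent to the unstated
rounding path of the original computation.

## Synthetic data generator

The generator emulates the four input table kinds at the study's reported
conditions; its defaults are those conditions, not tuning knobs.

* **Traits.** Mass and area are independent log-normals (positive,
  right-skewed, median ≈ mean, as observed); no distribution family is
  published, so log-normal is a modelling choice. Parameters are matched to
  the target median and IQR in closed form: for median *m* and IQR *r*,
  σ = asinh(r/2m)/z₀.₇₅. Terminal velocity is linear in the resulting wing
  loading plus Gaussian noise, with the slope set so wing loading explains
  ~80 % of velocity variance and the median pinned to the group target
  (11.0 mg / 0.56 cm² / 1.62 m/s natural; 21.5 mg / 0.966 cm² / 1.72 m/s
  artificial). Draws are floored at 0.2 m/s to stay physical.
* **Launches.** 37 launches, batch sizes uniform on 8–20, maximum wind
  uniform on 0–9 m/s; per-propagule distance = gradient model at
  α_true = 0.29 plus spread-model Gaussian noise floored at zero. The
  launch's mean/median winds are fixed fractions (0.8/0.75) of its maximum
  — their joint structure is not published and nothing downstream uses them
  beyond ordering constraints.
* **Wind series.** 30-min records over a 92-day season; Weibull(k=2) mean
  speeds, proportionally inflated gusts (gust ≥ mean per record), and an
  optional exact rescaling of the seasonal maximum gust (to emulate a
  station's seasonal maximum such as 16 or 23 m/s).
* **Drop trials.** Five stopwatch replicates per propagule from 2.68 m with
  3 % multiplicative timing noise.

What the generator does **not** emulate: gust micro-structure and temporal
autocorrelation of real wind, measurement rounding of tapes and stopwatches,
within-umbel trait correlation, and any distance noise beyond the linear
spread model. Passing tests therefore demonstrate internal consistency of
the models and estimators under the stated statistical structure — not
validation against field data, which requires the archived launch dataset
(supported through the same CSV schemas).

## Numerical and interface choices

* Quartiles/IQR: linear interpolation of the empirical distribution
  (numpy default); median of an even replicate count is the central-pair
  midpoint. The original quantile rule is unstated; this one is fixed and
  documented.
* Trait→velocity regressions are untransformed OLS with intercept; a
  constant response yields slope ≈ 0 and R² = 0 (not NaN).
* The per-α sweep uses closed-form OLS from sums for speed; statsmodels
  backs the trait regressions and provides standard errors there.
* CSV schemas use exact header names; validation errors cite the 1-based
  data row and column. Machine outputs carry 2-decimal distances; integer
  rounding appears only in the human-readable `ldd` report.
* Problem sizes in the test suite and acceptance script (100 replicate
  calibrations, 10⁴-propagule kernels, 10³-draw quadrature sweeps) were
  chosen as the smallest sizes at which the Monte Carlo error is an order
  of magnitude below the tolerances being checked.

## Known limitations

Single plant in open flat terrain; no turbulence, updrafts or obstacle
wakes; no post-landing transport; kernel distances are radial magnitudes
with no direction; the Hellmann profile with a single α is a coarse
summary of real boundary-layer structure, and α itself varies with
atmospheric stability on sub-daily timescales.
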