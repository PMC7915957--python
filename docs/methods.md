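# Methods

## Model

Hourly biogas production Y (m³ h⁻¹ at standard conditions) is regressed on
current and past substrate feeding X (kg h⁻¹):

    Y_t = α + Σ_r Σ_{j=0..k} β_{r,j} X_{r,t−j} + ε_t

with one coefficient vector β_r per regressor (solid feed always; liquid
feed optionally). Lag 0 is included: feeding is recorded at the hour it
occurs and may contribute within that hour. Estimation is ordinary least
squares on the T most recent observations; the model is refitted at every
forecast origin, which is the entire adaptation mechanism — there are no
state variables, no autoregressive terms, and no mechanistic digestion
submodel.

Assumptions this buys and their price:

* **Linearity and time-invariance within the training window.** The digester
  is treated as an LTI system over the last T hours: gas response is
  proportional to mass fed and additive across feedings. Inhibition,
  saturation, temperature or retention-time effects are only captured to the
  extent that rolling refits track them.
* **Exogenous feeding.** Feeding is an input, not a fed-back control signal;
  the forecast for a planned schedule is a direct evaluation of the fitted
  equation, so multi-step simulation needs no recursion and forecast error
  does not compound by construction — it grows only because the fitted
  coefficients age relative to a drifting process.
* **Interpretability.** No regularisation and no standardisation, so β stays
  in m³ kg⁻¹ per hourly lag bin and the lag profile is directly a
  gas-formation curve. The price is variance: T must comfortably exceed the
  1 + Σ(k+1) parameters (the canonical settings use 200–800 observations for
  50–97 parameters).

## Parameters that matter

| parameter | meaning | default | why |
|---|---|---|---|
| k (`lag_order`) | hours of feeding history entering the regression | 48 | silage-like substrates release most gas well within 48 h; grid also explores 72, 96 |
| T (`training_length`) | observations per fit | 500 | long enough for ~50 parameters, short enough to track current conditions; grid explores 200, 800 |
| H (`horizon`) | forecast length, hours | 48 | one feeding-planning cycle ahead; grid explores 96, 144 |
| step | rolling cadence | 24 h | one refit per day, the operational planning rhythm |
| `clamp_nonnegative` | floor simulated production at 0 | on for simulation | production is physically non-negative; off for all coefficient/residual analysis so the algebra stays linear |

## Numerical choices

* OLS is solved by column-pivoted QR (never the explicit normal-equations
  inverse). Rank is checked against a tolerance of 1e-10·‖X‖; a deficient
  design raises an error naming the offending columns. This is deliberate:
  windows with no feeding at all, or with exactly periodic dosing, occur in
  practice and must fail loudly rather than return arbitrary coefficients.
  The normal-equations solution serves as an independent oracle in the test
  suite, as does statsmodels OLS.
* The cross-correlation estimator uses full-sample (1/n) standard deviations
  in the denominator — the convention of standard time-series CCF routines —
  with the white-noise significance bound z₀.₉₇₅/√n. Positive lag means
  feeding leads production.
* MAPE divides by the observation, and plant data contain genuine
  zero-production hours (downtime), so observed-zero hours are excluded from
  the MAPE sum (E reduced accordingly, exclusion count reported) while
  remaining in MAE/RMSE. A window that is entirely zero makes MAPE undefined
  and the run is recorded as failed, not dropped.
* The area under the coefficient curve is a unit-width Riemann sum (β is
  already a per-hourly-bin quantity); no trapezoid or spline. The intercept
  is reported next to the yield but never added into it — it absorbs
  baseline/residual production, so curve-derived yields understate total gas
  potential. Every yield report carries this caveat explicitly.
* Run counts are never hard-coded: the number of valid rolling origins is
  ⌊(n − (T+k) − H)/step⌋ + 1, derived from the data extent (a calendar year
  at T=500/k=48/H=48/step=24 gives 341 origins).
* In the settings grid the three horizons share fits by default: each (T, k)
  pair is rolled once at the maximal H and shorter horizons are scored on
  prefixes of the same simulations, making the H comparison paired and three
  times cheaper. A flag restores fully independent runs per horizon.
* CSV I/O writes floats with `%.17g` and reads with round-trip float
  parsing, so a series survives write→read bit-exactly. Missing values never
  enter the data model; the reader's explicit repair mode (off by default,
  logged when used) forward-fills feeding and linearly interpolates
  production.

## The synthetic plant

The generator emulates the operating statistics of a full-scale research
digester:

* daily solid totals ~ Normal(5995.34, 2097.37²) kg d⁻¹ truncated at zero,
  split over 3–8 discrete feedings at daytime-weighted hours (06:00–20:00
  favoured 8:1); ~13 heavy events per year concentrate 65 % of a day's total
  into one >2,000 kg h⁻¹ feeding;
* the gas-response kernel `default_kernel(48)` is a two-phase exponential
  decay calibrated exactly (to 1e-12) to a total of 0.101 m³ kg⁻¹ with 62 %
  of the mass in lags 0–11; the fast phase has a 6 h time constant and the
  slow-phase geometric ratio is solved numerically, keeping the kernel
  non-negative and non-increasing;
* production = 45 m³ h⁻¹ baseline + kernel ⊛ feeding + N(0, 5 m³ h⁻¹),
  floored at zero. The baseline is chosen so mean production lands near
  70 m³ h⁻¹ (45 + 0.101·5995/24 ≈ 70.2), the noise s.d. is a realistic gas
  flow-meter figure of roughly 7 % of the mean signal;
* optional downtime (explicit intervals or a yearly rate) forces production
  to zero; it is off in the default scenario because downtime is a plant
  event outside the linear generating process, and clean defaults are what
  the exact-recovery oracles need;
* optional liquid-manure dosing at near-constant intervals and amounts
  (every 4 h, 800 kg, 5 % jitter). Its true gas kernel is zero by default:
  a steady stream's contribution is constant and belongs to the baseline.
  This reproduces the characteristic second-regressor pathology — liquid
  coefficients fluctuating around zero while the intercept soaks up the
  signal — and, with jitter set to zero, the exact-collinearity failure.

What the generator does *not* emulate: nonlinearity (inhibition,
saturation), seasonal or feed-composition drift, autocorrelated sensor
noise, sub-hourly dynamics, and any real within-day feeding schedule (the
daytime weighting is a plausible invention, flagged as such in the
ground-truth output). Passing tests therefore demonstrate that the
estimation machinery is correct and well-conditioned under the model's own
assumptions — not that a real digester satisfies them. On real data the
accuracy numbers are expected to be several times worse than on the
synthetic plant, precisely because those un-emulated effects exist; the
synthetic-year MAPE (~6 % at T=500/k=48/H=48) is in effect the noise floor
of the method, not a claim about plants.

One consequence documented here because it is easy to trip over: on the
*stationary* synthetic plant, mean RMSE is essentially flat in the horizon H
(per-hour forecast error does not grow with lead time when nothing drifts —
differences across H are within Monte-Carlo noise). Horizon error growth
appears as soon as the process drifts, because prefix-truncated simulations
score an aging model against increasingly different conditions; the property
test for horizon ordering therefore runs on a drifting variant (kernel gain
doubling over the year), where the ordering holds with a wide margin.

## Design choices that were genuinely open

* **Evaluation uses recorded feeding as the planned schedule** (hindcast):
  the quality question is "given the feeding that happened, how well is
  production simulated", which isolates model error from schedule error.
* **Failed fits are first-class**: singular origins appear in the run list
  with their error, count toward the origin total, and are excluded (with
  the success fraction reported) from cell means.
* **k = 0 is allowed** (plain linear regression) as the degenerate base case
  even though any real use starts at k ≫ 0.
* **Timestamps are labels.** The model runs on integer hour indices; the
  container enforces a gap-free hourly grid so the two views never diverge.
  No calendar effects are modelled.

## Known limitations

* OLS standard errors are not reported; residuals are autocorrelated by
  construction (hourly process data), so naive inference on β would be
  anticonservative. The ensemble spread across rolling runs is the honest
  variability summary and is what the kinetics module reports.
* Lag coefficients are not constrained non-negative, so fitted curves can dip
  below zero at poorly identified lags; the median across runs is used
  precisely because it is robust to this.
* The MAPE zero-exclusion rule makes MAPE incomparable across runs with very
  different downtime fractions; MAE/RMSE are the stable companions.
* `default_kernel` with the default 6 h fast phase is infeasible for
  k ≲ 33 at the default 62 % fraction (the slow tail cannot hold the
  remaining mass without exceeding the junction value); it raises a
  parameter error rather than silently reshaping.
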