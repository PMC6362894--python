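# Methods

## Model

The package projects age–sex–race–area population panels with
cohort-change operators rather than component rates.  Populations are held
in 18 five-year age groups (code `a` covers `[5(a-1), 5a)`; code 18 is the
open interval 85+), two sexes (1 = Male, 2 = Female), and a configurable
race registry (four-group by default: White NH, Black NH, Hispanic,
Other NH; a three-group White/Black/Other registry is provided for
validation-style layouts).  Area codes are opaque strings whose first two
characters name the state.

For destination ages 2–17 the operators are the cohort-change ratio
`CCR = P[a,t] / P[a-1,t-y]` (applied multiplicatively) and the
cohort-change difference `CCD = P[a,t] - P[a-1,t-y]` (applied additively).
The open interval is fed by the pooled 80-and-over population:
`CCR85 = P[85+,t] / (P[80-84,t-y] + P[85+,t-y])`, and the projected 85+
group is the forecast ratio (or difference) applied to the current 80+
pool.  Ages 0–4 are regenerated each step from the child-woman ratio,
CWR = population 0–4 (both sexes) / women aged 15–49, computed on pooled
sums at state × race level (a national × race fallback covers empty
pools); projected births use the women already projected within the same
step and are split male/female by srb/(1+srb) and 1/(1+srb) with the sex
ratio at birth srb = 1.05 by default.

### Forecasting

Every series — one CCR and one CCD history per (area, race, sex,
destination age), one CWR history per (state, race) — is fitted
independently as a driftless ARIMA(0,1,1),
`Y_t = Y_{t-1} + e_t - θ e_{t-1}`.  The one-step forecast is an
exponentially weighted moving average with weights `θ^k (1-θ)` — simple
exponential smoothing with weight `α = 1-θ` — and forecasts at all
horizons j ≥ 1 equal the one-step forecast, so a fitted series contributes
a single constant to every projection step.

Estimation choices, made here and recorded as the package's own:

* **Estimator.** The default minimises the conditional sum of squares of
  the differenced series with `e_0 = 0` (conditional maximum likelihood).
  This makes the smoothing equivalence *exact* in finite samples: the CSS
  forecast at parameter θ is algebraically identical to SES with weight
  `1-θ` started at the first observation, so the fit agrees with an
  independent SES grid search to grid resolution.  An exact Gaussian
  likelihood (innovations algorithm, profiled error variance) is available
  per series as `estimator="mle"` and is cross-checked against
  statsmodels' state-space ARIMA in the test suite.
* **Parameter space.** θ is constrained to [0, 0.999).  The upper bound is
  invertibility; the lower bound excludes negative θ, for which `α > 1`
  and the weight sequence `θ^k(1-θ)` is no longer a valid smoothing
  weighting.  Fits at the boundary are accepted.
* **Short and broken series.** Series with fewer than `min_len = 4`
  non-missing observations are forecast by carrying the last observation
  forward (`naive-last`); likelihood fitting on 2–3 points is ill-posed.
  Interior missing values (masked zero-denominator ratios) are dropped and
  the series compacted rather than interpolated.  Fully missing series are
  flagged `fallback-missing`.
* **Numerics.** The CSS objective is minimised by a vectorised grid search
  (199 points) with two nested local refinements (41 points each), giving
  θ to ~1e-5 across hundreds of thousands of series in milliseconds; a
  constant series short-circuits to θ = 0 and an exact forecast.

### Projection

Steps advance the panel by the census interval (y = 5 years by default).
Zero-denominator ratio cells are masked missing rather than set to 0 or ∞
— tiny cohorts otherwise produce arbitrarily explosive ratios — and a
ratio-mode cell whose forecast is missing substitutes the additive
difference for that cell.  Negative cells are floored at zero after each
step, before the next step consumes them (disable with
`floor_at_zero=False`).

The blended model classifies each (area, race) combination **once per
horizon** by running a provisional full-horizon pure-CCD projection:
additive differences are kept where the final provisional total is at
least the launch total (ties and degenerate all-zero areas count as
growth), ratios otherwise.  Re-evaluating the choice at each step could
flip operators mid-horizon; a single decision per combination matches the
per-combination phrasing of the rule and keeps trajectories monotone in
regime.

Group quarters are treated as structurally determined rather than
demographically evolving: the launch population is split into household
(total − GQ, clipped at zero, with a warning when GQ exceeds the total)
and GQ; the household part is projected; GQ is added back unchanged —
cell by cell, the strictest reading of holding GQ constant per
age/sex/race/area group — at every output year.

### Raking to scenario controls

Scenario control tables give age–sex totals per projection year.  Controls
distributed with a later open interval (e.g. 100+) are first truncated by
summing all codes ≥ 18 into 85+.  Raking multiplies each cell by
control/raw within its (age, sex, year) margin, independently per year; it
is therefore idempotent, preserves within-margin shares exactly, and does
not feed back into subsequent projection steps (the control is a static
per-year rescaling, not part of the dynamics).  A margin with zero raw
population but positive control is left at zero and the unallocated mass
reported — the method has no information to allocate it.  Raking operates
on real-valued populations; rounding (none or nearest) is applied only by
the output writer.

### Error metrics and validation harness

With `A` observed and `P` projected: APE = |A−P|/A, ALPE = (P−A)/A,
SAPE = |P−A|/(P+A).  The ALPE sign is chosen so over-projection is
positive, matching the interpretation of positive bias as over-projection;
a `strict_sign=True` flag restores the opposite convention.  SAPE is
defined as 0 at A = P = 0 (the zero-cell case it exists to handle) and is
1 when exactly one of the pair is zero.  APE/ALPE are undefined at A = 0;
such cells are excluded from medians and means and counted in the report.

`holdout_validate` fits the pipeline on a base period, launches from the
last base census, projects the holdout years with pure-CCD, pure-CCR and
blended variants (optionally a blended variant raked to the observed
age–sex totals), and summarises errors per holdout year at five levels:
joint age/sex/race/area cells (median SAPE), whole-population total,
per-area totals, per-age-group and per-race-group county totals (median
and mean APE/ALPE, pooled and per group).

## Synthetic data

The generator emulates the *structure* of US bridged-race county panels —
FIPS-like area codes nested in states, the 18-age ladder, both sexes, a
small race registry, censuses every 5 years — with known dynamics: one
constant (optionally linearly trending) true CCR or CCD per (area, race,
sex, destination age) and one true CWR per (state, race).  The initial
census draws uniform cell sizes (200–2,000) shaded by an exponential age
decay, with ages 0–4 made consistent with the true CWR so measured CWR
series are constant from the first census.  Evolution is written as a
plain loop, independent of the projection engine's vectorised stepper, so
each implementation checks the other.  Observation noise, when requested,
is mean-one multiplicative lognormal per cell and census (non-negativity
is automatic); the noise-free path is returned alongside as ground truth.

Default scenario: 6 areas in 2 states, 2 races, 7 censuses 1970–2000.
CCR dynamics default to Uniform(0.85, 0.98) — a gently declining system,
so the blend rule selects ratios — and CCD dynamics to Uniform(2, 40)
persons per step — steady growth, so the blend selects differences.  These
defaults make both exact-recovery directions testable; they are not a
demographic calibration.  What passing tests show is that the estimation,
forecasting, projection and control machinery is internally exact and
well-behaved under known dynamics; they say nothing about forecast
accuracy on real populations, which depends on how far real cohort-change
series deviate from the fitted trend model.

The Monte-Carlo validation study in the acceptance suite runs 200
replicates of the default scenario with σ = 0.10 observation noise, fits
on the first five censuses and scores the last two, verifying that median
joint SAPE grows with projection horizon and that the blended model's
per-area APE does not exceed the worse of the two pure variants.  Problem
sizes (6 areas, 820 series per replicate, 2 holdout steps) keep the full
study to a few seconds while leaving dozens of noisy series per fit.

## Known limitations

* The trend model is deliberately minimal: no drift term, no order
  selection, no prediction intervals — point projections only.
* Only the single age–sex margin is controlled; multi-margin iterative
  proportional fitting is out of scope.
* CWR pooling is exactly state × race; no smoothing or pooling of CCRs
  across counties is performed.
* The synthetic generator does not attempt realistic US age schedules,
  spatial correlation, or boundary changes, and the validation harness has
  not been run against the full historical US county panel, which is an
  external download.
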