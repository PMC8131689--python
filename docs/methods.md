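# Methods

## Scope and model

`cacaoflow` implements the analysis chain for predicting volumetric sap flow
(V_s, L h⁻¹) of cacao trees growing under three agroforestry (AF) shade
regimes — labelled `H_PAR`, `M_PAR`, `L_PAR` for high / medium / low
transmitted radiation — from four under-canopy microclimatic covariates:
air relative humidity RH_a (%), air temperature T_a (°C), photosynthetically
active radiation PAR (µmol m⁻² s⁻¹), and vapor pressure deficit VPD (kPa).
The prediction model is linear with a full coefficient set per AF,

    V_s = β₀(af) + β₁(af)·RH_a + β₂(af)·T_a + β₃(af)·PAR + β₄(af)·VPD ,

estimated as a single dummy-interaction design (15 fixed-effect columns)
with crossed random intercepts for plant and calendar day, by REML.
Positive V_s is acropetal flow; negative values are basipetal flow, the
field signature of nocturnal hydraulic redistribution.

## Heat Ratio Method processing

Raw sensor readings are the ratio of the temperature rises at two
thermocouples equidistant downstream/upstream of a heater pulse, at 5 and
20 mm behind the cambium.  Heat pulse velocity is

    V_h = (k/x) · ln(T1/T2) · 3600   [cm h⁻¹],

with thermal diffusivity k = 0.0025 cm² s⁻¹ and spacing x = 0.6 cm by
default.  Although V_h is sometimes annotated in m s⁻¹ in the source
literature, these units and the 3600 factor yield cm h⁻¹, the standard HRM
convention, which we use throughout.  Velocity converts to flow through the
sapwood properties,

    V_s = (ρ_b/ρ_s) · (m_c + C_w/C_s) · V_h · S / 1000   [L h⁻¹],

with the cm³ h⁻¹ product divided by exactly 1000.  C_w = 1200 and
C_s = 4186 J kg⁻¹ K⁻¹ are literature values at 20 °C; ρ_b (500 kg m⁻³),
m_c (1.0) and S (40 cm²) are not reported for these trees and are
configuration values used by fixtures only.  Design choices where the
source was silent:

* **Depth merging** — the two installation depths are combined by an
  unweighted mean (weights configurable).
* **Wound correction** — a cubic polynomial a·V_h + b·V_h² + c·V_h³ with
  identity default (1, 0, 0): no correction is fabricated where no
  coefficients were published.
* **Zero offset** — the stem-cut calibration is a baseline window whose
  mean velocity is subtracted (idempotent).
* **Daily totals** — trapezoidal integration per interval, split exactly at
  midnight; intervals longer than a configurable gap (default 30 min) are
  not integrated and flag the affected days.  Gaps are never interpolated.

## Microclimate and VPD

VPD uses the FAO-56 instantaneous formulation, e_s(T) = 0.6108·exp(17.27·T/
(T+237.3)), VPD = e_s·(1 − RH/100), computed per minute-level sample
*before* any averaging.  Because e_s is convex, the mean of minute-level
VPD over an hour is not the VPD of the hourly-mean inputs; both tests and
the generator treat this nonlinearity explicitly.  A daily max/min
estimator (the other FAO-56 recipe) is provided for comparison, because the
published hourly VPD means are only consistent with that method: at the
daytime slots, instantaneous VPD evaluated at the published T/RH means
exceeds the published VPD means by 0.15–0.35 kPa, more than their standard
errors.  No choice of day-to-day T–RH covariance can close that gap (it
would require a correlation above +1), so the generator calibrates RH, T
and PAR to the published slot statistics and lets VPD follow from physics;
the resulting VPD means are pinned in a regression test as *higher* than
the printed ones.

Slot summaries report mean ± SE (SD/√n) per AF × hour-of-day; PAR is
omitted for night slots.  All hour logic is local time (the study site is
UTC−5; timestamps are generated in local time).  Day/night classification
defaults to local hour ∈ [06:00, 18:00), with a PAR-threshold alternative
(day iff PAR > 5 µmol m⁻² s⁻¹).  AF comparisons per slot use a one-way
omnibus F test followed by Fisher's LSD pairwise t-tests on the pooled
within-group variance; compact letters are assigned by descending mean.
The source used α = 0.01 in its methods text and 0.05 in its table caption;
α is a config value, default 0.05.

## The synthetic campaign

No field data are distributed, so the generator reproduces the *published
statistical structure* rather than any particular realization:

* **Diurnal shapes.**  Monotone piecewise-cubic (PCHIP) arcs through the
  six published slot anchors (10:00, 13:00, 16:00, 20:00, 00:00, 04:00),
  periodic over 24 h for RH and T; PAR uses a day arc pinned to zero at
  06:00 and 18:00, so night PAR is exactly zero.  Anchor values are
  adjusted iteratively until the *hourly mean* over each anchored slot
  equals the published mean (evaluating the curve at the slot centre is not
  enough, since the curve bends within the hour).
* **Day-to-day weather.**  One standardized day factor, shared by all AFs
  (the site is one location), raises T and PAR and lowers RH on clear days.
  Its per-variable amplitude envelope is the published slot SE × √14
  (14 monitoring days), interpolated across hours — i.e. the day-to-day
  spread is calibrated so the SE of a slot mean over the campaign matches
  the published SE.  Day factors are centred across days, so slot means
  stay exactly on target.
* **Minute jitter.**  AR(1) noise (ρ = 0.7 per minute) per variable, with
  heteroskedastic scale: T ±0.3 °C; PAR relative (10 % of the profile,
  zero at night); RH scaled by 0.25·(100 − profile) capped at 1.5 %, so
  near-saturated nights have the tiny variance they show in the field and
  clipping at 100 % is negligible.  Jitter is centred per AF × hour cell,
  again protecting the slot-mean calibration.
* **Sap flow.**  The noiseless signal is the linear model evaluated on the
  generated covariates with the *reconciled* published coefficient set
  (below), through the same code path as `model.predict`.  Four plants per
  AF log ~every 15 min (5556 rows per AF over 14 days — 3816 for fitting
  plus 1740 for validation, the published sample sizes).  Observations add
  a per-plant intercept (SD 0.005 L h⁻¹), a per-calendar-day intercept
  (SD 0.005, shared across AFs), and white noise of SD 0.015 L h⁻¹, the
  midpoint of the published RMSE range (0.01–0.02 L h⁻¹).
* **Inverse HRM.**  Any flow series can be mapped back to temperature
  ratios (ratio = exp(V_h·x/(3600·k)) after inverting the sapwood factor),
  giving raw-sensor fixtures whose round trip through the processing
  pipeline is exact to < 1e−9 L h⁻¹.

What the generator does *not* emulate: rain events and synoptic weather
beyond a single day factor, soil-moisture dynamics, sensor drift and
misalignment, wound growth, or any nonlinearity in the V_s–microclimate
relationship.  Passing tests therefore demonstrate that the pipeline
recovers what it assumes — a linear signal with the published first and
second moments — not that real cacao sap flow is linear in its drivers.

### The reconciled coefficient set

The published coefficients appear in two forms: reference-coded (H_PAR
baseline plus M/L differences) and per-AF absolute.  Summing baseline and
difference reproduces every absolute *slope* to 1e−5, but the absolute
*intercept* rows repeat the raw differences (M_PAR 0.37090, L_PAR
−0.04641) instead of the sums (0.51994, 0.10263).  Only the summed
intercepts reproduce the reported per-AF nocturnal behaviour (H_PAR
+0.039 L h⁻¹ at its published 04:00 conditions, L_PAR −0.030 against a
reported −0.0314 ± 0.004), so the generator uses slopes-as-printed with
summed intercepts.  Both sets ship in `cacaoflow.reference`, and the
inconsistency is pinned by tests rather than hidden.

A known consequence of taking the printed coefficients at face value:
the M_PAR PAR slope (0.00057) times midday PAR (~560) yields midday flows
near 0.45 L h⁻¹, larger than any observed flow the study reports —
collinearity in the original fit is the likely cause.  Recovery tests are
self-consistent regardless; the feature is documented, not "fixed".

## Estimation and diagnostics

* **Fitting.**  statsmodels `MixedLM` with the two random factors expressed
  as variance components on a single grouping (crossed intercepts; a nested
  day-within-plant option exists).  Optimization uses Powell's method: on
  boundary problems (true variance components at zero) the gradient-based
  optimizers stall at spurious interior points, while Powell reaches the
  boundary optimum, where the REML fixed effects agree with plain OLS to
  1e−6 (unit-tested).  A pure OLS fallback is always available.
* **Inference.**  Wald z statistics on fixed effects; slope differences
  between AFs are contrasts on the fitted covariance.  AIC/BIC are computed
  as −2·logLik + 2p and −2·logLik + p·ln(n) with p counting fixed effects,
  variance components and the residual variance; rankings break ties toward
  fewer parameters.
* **Partial residuals.**  Raw residual plus the fitted per-AF component of
  one covariate; curvature is flagged when the quadratic coefficient of a
  follow-up regression on the centred covariate is significant (default
  α = 0.01).  Quadratic candidate models centre covariates before squaring
  to limit collinearity.
* **Validation.**  RMSE, percent bias (positive = overprediction), NSE, and
  the regression of *observed on predicted* (observed on the y-axis), with
  a t-test of slope against 1.  The holdout is the chronological tail by
  default (the published fit/validation sizes 3816/1740 correspond to
  fraction 1740/5556); a seeded random mode exists.  The reversed-flow
  proportion is volume-weighted: 100 × |∫ negative flow dt| / ∫ |flow| dt
  over the full day, not a sample count.

## Numerical contracts and degenerate inputs

Generation is deterministic given the seed (regeneration agrees to
< 1e−12; in practice bit-identical).  Non-positive temperature ratios,
RH outside [0, 100] (unless a logged lenient clip is enabled), unsorted
timestamps, empty baseline windows, mismatched depth keys, singular
designs (reported with the collinear column names), zero-variance
observations in NSE, and constant covariates in partial residuals all
raise errors rather than propagate silently.  Random factors with fewer
than two levels are dropped with a warning; single-sample slots report
SE 0 with a degeneracy flag.

## Known limitations

* The generated L_PAR signal spans only ≈ −0.03 to +0.08 L h⁻¹, so at the
  0.015 L h⁻¹ noise level its observed-vs-predicted R² saturates near
  0.88–0.92 rather than the 0.95+ reached by H_PAR and M_PAR; the test
  suite records this bound honestly.  See the coefficient-set notes above.
* The synthetic M_PAR nocturnal mean is slightly positive (≈ +0.003
  L h⁻¹, within the published −0.0047 ± 0.0085) because the evening
  humidity trajectory between the 16:00 and 20:00 anchors is not
  constrained by any published statistic; its sign flips with the (also
  unpublished) day/night boundary.
* Wound-correction coefficients and sapwood properties are placeholders;
  results in physical units depend on supplying real values.
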