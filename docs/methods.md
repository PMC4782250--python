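# Methods

## The energy balance and the three activity models

Daily consumption is modelled as `C = (AMR + G) / A` in J g⁻¹ day⁻¹.
`A = 0.685` is interpreted as the *retained* (assimilated) fraction of
consumed energy, so the metabolic and growth requirements are divided by it
to recover gross intake; reproduction is fixed at zero (juveniles), though
`consumption()` accepts an optional additive term.  Growth energy is
`G = (Gv/W)·Fj` with the daily growth rate `Gv` taken from the parameter
table; a von Bertalanffy helper (`vb_growth_rate`) can derive `Gv` from
growth-curve and length–weight coefficients, but it is a convenience — the
tabled value is authoritative, and the helper refuses to run without
explicit length–weight coefficients.

Active metabolic rate comes from one of three models.

**Accelerometry.**  Laboratory swim-tunnel respirometry calibrates
`MR = s·e^{b·Act}` (mass-specific rate, mgO₂ kg⁻¹ h⁻¹, vs transmitted RMS
acceleration).  Field activity is reduced to mean hourly activity in a day
(07:00–18:59) and a night period, each converted to metabolic rate and
weighted by its 12 hours, then converted to energy with the oxycalorific
coefficient (14.14 J mgO₂⁻¹).  The exponential form guarantees a positive
extrapolated resting rate at zero activity; a linear form does not (its
fitted intercept is negative), which is why form selection matters.

**Morphometric.**  Routine swimming speed is predicted from standard
length and caudal-fin aspect ratio via a log₁₀-linear multi-species
regression (in km h⁻¹, converted to m s⁻¹), then converted to metabolic
rate through the calibrated `MR = r·e^{z·SS}` and scaled to 24 h.  The
parameter table's `Speed` row (0.7245 m s⁻¹) is retained as a reference
value only: the model derives speed from the regression per evaluation,
which at the table means gives 0.560 m s⁻¹.  The discrepancy is inherited
from the source parameterisation (plausibly a different length input); we
evaluate the regression exactly as printed with `SL = 49` cm and expose
the length input in the registry.

**Physiological.**  `R = R_a·W^{R_b}·e^{(ln Q10/10)·T}·AM` in
gO₂ g⁻¹ day⁻¹, a Wisconsin-style formulation: an allometric mass-specific
standard metabolic rate, a Q10 temperature factor, and a fixed activity
multiplier `AM = 2` standing in for the cost of activity.

All unit conversions (km h⁻¹→m s⁻¹ = 1/3.6, J kg⁻¹→J g⁻¹ = 10⁻³,
gO₂→mgO₂ = 10³) are module constants in `bioenergetics`.

## Calibration fitting

Respirometry records (optionally reduced from per-stage dissolved-oxygen
drawdowns in a sealed 690 L tunnel; stages ending below 80 % saturation are
excluded) are fitted on the log scale as linear mixed models with a
per-fish random intercept, by maximum likelihood — not REML — so AICc is
comparable across fixed-effect structures.  Whole-animal rates are made
mass-specific with a scaling exponent of 0.79, and nominal speeds receive
the solid-blocking correction `ε = τλ·(A_fish/A_chamber)^{3/2}` with
`τλ = 0.8` by default (the cited correction's formula is not printed in the
source; this is the standard swim-tunnel form, exposed in the API).

Form comparison (exponential vs linear) computes
`AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1)` with `k = 4` (two fixed effects plus
two variance components — our convention, stated explicitly because the
variance-component count is not standardised).  Because the exponential
model is fitted to `log MR`, its likelihood is mapped to the raw response
scale through the Jacobian of the log transform (subtracting `Σ log y`)
before comparison; without this the two forms' likelihoods are not
defined on the same space.  Degenerate inputs degrade gracefully: a
single-fish design falls back to OLS with a warning, and a singular fit
returns `random_intercept_sd = 0` rather than raising.

## Field processing

Detections are excluded if recorded outside the calibrated temperature
window (24 ± 1 °C by default) or within 24 h of release (burn-in takes
precedence when both apply); kept and excluded frames partition the input
exactly, making the filter idempotent.  The diel summary averages within
hour-of-day bins first and then across the 12 bins of each period, so
variation in detection rate through the day cannot bias the period mean;
a pooled mean and a per-fish-first mode are flags.  The printed period
definitions (07:00–18:00 day, 19:00–06:00 night) leave two boundary hours
unassigned while both periods are 12 h long; we assign [07:00, 19:00) to
day and the complement to night so the 24-h budget closes.  An optional
`max_activity` guard warns when a period mean exceeds the calibrated
activity range.

## Monte Carlo propagation

Each model's parameters are sampled independently from normal
distributions at the registry mean/SD, 10,000 iterations by default.
Structural constants (`h_d`, `h_n`, `AM`) are held at their means.  Draws
violating hard domain constraints (`A ∉ (0,1]`, `W ≤ 0`, `AR ≤ 0`,
`SL ≤ 0`, `Q10 ≤ 0`, `Fj ≤ 0`) are rejected and redrawn (keeping n fixed);
with the packaged table the redraw rate is ~0.2 %, dominated by the mass
column's wide SD.  No parameter covariance is imposed — the calibration
fit's intercept/slope covariance exists but correlated sampling is
deliberately not the default, matching the independent-normal design.
The AR distribution is sampled untruncated apart from the positivity
constraint.  A log-normal is fitted to the draws by maximum likelihood
(mean and SD of log draws); the summary also reports the arithmetic mean,
the empirical median, a Monte Carlo SE, and a running-SD trace as a
variance-stabilisation diagnostic.

**Heavy-tail caveat.**  The morphometric and physiological models
exponentiate wide normal inputs (`z·Speed` with derived speed spanning
well past the 0.1–0.8 m s⁻¹ calibrated range; `R_b·ln W` with
SD(R_b)=0.11), so their *arithmetic means* are dominated by a small number
of extreme draws (expect means near 200–350 and 250 respectively, varying
strongly with seed), while their medians (~119, ~178) and log-scale SDs
(~0.61, ~0.79) are stable.  The fitted-log-normal mean
`exp(μ + σ²/2)` consequently tracks the arithmetic mean only for the
accelerometry model (within ~2 %), and the across-model ordering of
arithmetic means is not stable even at n = 10,000.  Medians and σ are the
robust summaries; `run_monte_carlo(..., max_speed=0.8)` offers an
extrapolation guard for the morphometric model that removes the speed tail
(at the cost of shrinking σ), off by default.

## Sensitivity analysis

Per iteration every parameter of a model independently takes one of
{mean·0.9, mean, mean·1.1} with equal probability (a two-level ±10 % mode
is a flag); consumption is evaluated per iteration; inputs and output are
z-scored and an ordinary multiple regression yields standardized
coefficients.  The hour budget is never perturbed (it would break the 24-h
day); the activity multiplier is perturbed like any other parameter;
constant columns are dropped and reported.  With the packaged table the
intercepts `log_s`/`log_r` dominate their models and `Q10` dominates the
physiological model; `W` and `A` are the only negative coefficients; the
growth-side parameters `Gv`, `Fj` and `W`'s growth pathway are near-exact
ties at the bottom (|coefficients| within ~0.001 of each other, below the
regression's Monte Carlo resolution of ~0.003 at n = 10,000), so claims
about which of them is strictly smallest are resolution-limited.

## Synthetic data

The respirometry generator reproduces the calibration design: 7 fish ×
8 speeds (0.1–0.8 m s⁻¹, 15-min stages), per-fish random intercept SD
0.18, residual SD 0.10 on the log scale, and a linear speed→activity link
with slope `z/b = 1.201` and intercept `(log_r − log_s)/b = 0.370` m s⁻²
chosen so the activity- and speed-based fits recover their respective
published coefficient pairs from the same records; activity noise SD is
0.10 m s⁻² (realistic between-measurement scatter in RMS acceleration at a
fixed speed, and enough independent variation to identify the activity
slope separately from speed).  Masses are uniform on 1.2–2.5 kg and fish
occupy 10–15 % of the tunnel cross-section, so blocking corrections are
exercised.  The detection generator transmits every 50–100 s, thins to a
detection probability of 0.052 (≈60 detections per fish-day, the reported
field rate), uses a square-wave diel mean (day 1.582, night
0.808 m s⁻²) with 30 % multiplicative noise floored at zero, and draws
temperatures N(24, 0.4 °C) so the temperature filter bites slightly.

What the generators do *not* emulate: within-period activity
autocorrelation (draws are i.i.d. given the hour), detection-efficiency
structure (thinning is uniform), temperature–activity dependence, and any
nonlinearity in the speed→activity link.  Passing recovery tests therefore
demonstrate correctness of the estimators under the assumed structure, not
robustness to these real-data features.

## Problem sizes and numerical choices

Monte Carlo and sensitivity runs use the prescribed 10,000 iterations;
calibration-recovery checks use 200 replicate experiments of 56
observations, and field-fidelity checks pool ten 10-day campaigns — sizes
at which every check completes in seconds while keeping Monte Carlo error
well below the tolerances tested.  Random draws all flow through
`numpy.random.default_rng` seeds; equal seeds give bit-identical results.
Ties in AICc produce equal Akaike weights; `fit_calibration` requires
n > k + 1 = 5 observations for AICc to exist; registry round-trips write
floats via `repr` so values survive bit-identically.
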