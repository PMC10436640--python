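# Methods

This package re-implements, as a tested pipeline, the evaluation machinery
of an internet-based pharmaceutical-care (IPC) study in young and
middle-aged hypertension: questionnaire scoring and blood-pressure
control classification, a PCA/Hotelling-T² questionnaire-reliability
screen with contribution diagnostics, OPLS-DA S-plot/VIP variable
selection, and a 3-state Markov cohort cost-effectiveness model with
one-way sensitivity analysis.  The patient-level data are not deposited,
so a synthetic-cohort generator reproduces the published summary
structure and stands in for them.

## Scoring and endpoint definitions

The 25-item compliance questionnaire (Q1–Q14 medication compliance,
Q15–Q25 living habits) uses a 5-point Likert scale.  Items Q1 and Q6–Q13
— nine items — are negatively worded and reverse-coded as `x -> 6 - x`
(the standard 5-point reversal; the study names the items but not the
formula).  The adjusted total lies in [25, 125].  Blood pressure counts
as controlled when SBP ≤ 120 mmHg **and** DBP ≤ 90 mmHg, both thresholds
inclusive as quoted; "measured at home during nighttime" is treated as
metadata.  Control rates are percentages rounded half-up to two decimals
(69/96 → 71.88, 31/96 → 32.29).  A questionnaire is time-acceptable iff
its completion time is strictly under 10 minutes.

## Synthetic cohort generator

The generator emulates the followed cohort: 96 patients (49 male /
47 female), four questionnaires at months 0/3/6/12, one patient (chosen
uniformly) missing the last two rounds.  Per sex it draws age
(45.84 ± 9.62 / 47.33 ± 10.84 y, clipped to the 18–65 enrollment window),
baseline DBP from a truncated normal, and SBP as DBP plus an independent
pulse pressure, which enforces `sbp > dbp` while matching both marginal
means and (approximately) both SDs.  From month 3 the configured
intervention effect (−13 mmHg SBP, −7 mmHg DBP, stable thereafter) is
applied; repeated readings add 4 mmHg measurement noise.

Item scores come from a latent-trait model chosen as the simplest
mechanism that makes item-level variable selection meaningful: a
per-patient latent adherence level (correlated across timepoints with an
exchangeable coefficient, default 0.7 — the study reports no
within-patient correlation, so it is a config knob), plus independent
per-item noise (SD 0.8 points), discretised to the 1–5 grid.  Because
rounding and clipping bias raw moments, the latent item mean is solved
numerically (Brent root-finding on the exact discretised-mean function)
so the *discretised* item mean hits its target; the patient-level SD is
set from a delta-method variance split so the total-score SD
approximates the configured 12.90/15.17 points.  The questionnaire
improvement (+15 points by month 12, linear ramp over the year) is
carried entirely by a designated 10-item set (default: Q1, Q6, Q7 —
reverse-coded — plus Q15–Q21), mirroring the ten improved questions the
study reports; their identities are not machine-readable in the source,
so the default set is a design choice.  Items are generated on the
adjusted scale and mapped back, so reverse-coded improved items improve
by *decreasing* raw score.

Completion times are zero-truncated normals reparametrised so the
truncated mean equals the configured per-round mean (1.95/6.25/5.03/4.20
min); plain truncation would bias the shortest round upward by ~1 min.

Known departures from real data, hence what passing tests do not show:

- The configured +1.5-point improvement per improved item drives those
  items into the 5-point ceiling by month 12: their realised gain is
  ~+10 of the configured +15 total points and their month-12 variance is
  near zero.  Real Likert data would show the same ceiling more
  gradually.
- The published post-intervention BP means (≈125/85 ± 13) are
  statistically inconsistent with the published 71.88% control rate
  under the ≤120/≤90 definition, so the generator — which matches the
  published moments — yields lower threshold-based control rates
  (~35–40% at month 12).  Control-rate arithmetic is therefore exercised
  on constructed flag vectors, exactly as the source reports counts.
- No seasonality, device error, medication data, or age-dependent risk.

## PCA reliability screen

Each questionnaire round (rows = patients; columns = 25 adjusted items
plus SBP and DBP — the study does not say whether BP entered, so the
variable list is configurable) is mean-centered and unit-variance scaled
(the SIMCA default; pareto and no scaling are available).  Zero-variance
columns are dropped with a warning.  A two-component PCA is extracted by
NIPALS with deflation (convergence at 1e-10 relative score change or 500
iterations); components equal the dense eigen-solution on full-rank
matrices and requests past the effective rank truncate with a warning.

Hotelling's T² per patient is `sum_a t_a² / var(t_a)` over the A = 2
components, with the control-ellipse limit

    T²_crit = A (N−1)(N+1) / (N (N−A)) · F_{1−α}(A, N−A),   α = 0.01,

which tends to the χ²_A quantile as N grows.  A round passes when at
most 10% of patients fall outside (per-round, as the study reports it).
Flagged patients get a score-distance contribution profile:
`c_k = x_pre,k · Σ_a (|t_a|/var(t_a)) |p_ka|`, i.e. the preprocessed
deviation weighted by loading magnitude over the components on which the
patient is extreme.  The sign is the sign of the deviation (a below-mean
value contributes negatively), an observation at the column means
contributes zero everywhere, and on block-structured data the injected
block dominates the profile.  Residual-distance (DModX) diagnostics and
cross-validated component selection are out of scope.

## OPLS-DA and variable selection

The before/after comparison stacks each complete-case patient's month-0
and month-12 rows (the dropout is excluded pairwise), encodes
"after" = +1, and fits O-PLS: per orthogonal component (default 1) the
predictor variation orthogonal to the class vector is removed, then a
one-component PLS1 gives the predictive score t_p.  Orthogonal scores
have exactly zero covariance with the class vector by construction, and
with zero orthogonal components the model is plain PLS1.

S-plot coordinates are `p_cov(k) = cov(t_p, x_k)` and
`p_corr(k) = p_cov(k)/(sd(t_p) sd(x_k))` against the preprocessed (not
orthogonal-filtered) matrix.  VIP for the single predictive component is
`sqrt(K)·|w_k|` with w of unit norm, so mean(VIP²) = 1 identically.
Because a classical VIP is nonnegative, the study's "VIP < −0.5" is
implemented as a *signed* VIP — VIP times the sign of the S-plot
covariance — thresholded at |signed VIP| ≥ 0.5, which reproduces the
reported sign semantics (SBP negative = decreased after intervention).

mean(VIP²) = 1 has a consequence: on a zero-effect cohort the VIP
threshold alone still selects many variables (VIP ≈ 1 spreads over all
of them), because a single-split predictive score overfits at the
`sqrt(K/n)` correlation scale.  Selection therefore also requires the
S-plot reliability gate |p_corr| ≥ 0.35.  The gate was calibrated once
on the generator's study conditions — large enough that zero-effect
cohorts yield a near-empty selection (median ≤ 2 false positives), small
enough that the −13 mmHg SBP effect (|p_corr| ≈ 0.4) survives — and then
frozen; the raw VIP-only set is still reported alongside.  Permutation
tests, Q² and CV-ANOVA are out of scope, matching the source.

## Markov cohort model

Three states: poorly controlled, well controlled, death (absorbing).
Cohort of 96, mean start age 46.63 y, 28 annual cycles (the gap to the
75.26-y life expectancy), everyone starting poorly controlled.
Poor-state mortality is P_MH = 0.2750 × 0.455 × (1.8279/2.815) = 8.12%
per cycle (the unrounded product is used; a calibration switch can add
natural mortality on top).  Well-state mortality is the 7.18‰ natural
rate.  Within a cycle deaths occur first, then survivors transition —
the only ordering consistent with the published cycle-1 counts (8 deaths
from 96; 63 = 71.88% of the 88 survivors).

The transition structure was reverse-engineered from the published
cohort table.  Neither pure redistribution of survivors (well→well with
probability c) nor pure incremental accrual (well survivors always stay)
matches the table beyond cycle 1.  What reproduces every parseable row
of both arms — cycles 0–3 and 28 — is a *relapse* structure: poor
survivors become controlled with the arm's control probability
(0.7188 IPC / 0.11 without), and controlled survivors relapse to poor
control with the population hypertension incidence rate (0.275).  All
three styles are implemented (`relapse` is the default; `redistribute`
is the special case relapse = 1 − c, `incremental` relapse = 0).

Counts are largest-remainder rounded per cycle so each row re-sums to
96, which reproduces the published table exactly, including the
intervention arm's terminal (11, 30, 55).  The terminal fractions
(11.91 / 31.15 / 56.94%) agree with the published 11.92 / 31.06 / 57.02
to ≤ 0.15 points; the residual is internal to the original software's
settings and not recoverable from the text.

Life years are the alive occupancy summed under a cycle-accounting
convention.  The enumerated conventions (end-of-cycle, include-cycle-0,
half-cycle) all miss the published survival pair by ≥ 0.6 y under the
table-consistent dynamics; adding the equally standard *begin-of-cycle*
counting (occupancy at cycle starts 0..27) reproduces it essentially
exactly — 13.222 vs 13.22 without intervention, 18.633 vs 18.62 with,
incremental 5.410 vs 5.40 — so the calibration (re-runnable via
`calibrate_life_year_convention`, driver `analysis/05`) freezes
begin-of-cycle as the default.  QALYs weight occupancy by state
utilities; both default to 1 because the published QALY gain equals the
life-year gain exactly, implying unit weights.

Costs: the published ¥470.37 cumulative cost is not derivable from the
published ¥77.80/patient/year under any stated accrual (per-alive gives
≈ ¥1 449).  Accrual per *poorly-controlled* patient-year comes closest
(¥457.6 under the default convention, ~2.7% off) and is the default
basis; basis and discount rate remain knobs and the figure is flagged
calibration-dependent.  The cost-effectiveness ratio is cost over
incremental QALY (undefined — not a ratio — when the increment is not
positive) and is compared inclusively against the ¥57,700 one-time
per-capita-GDP willingness-to-pay threshold.  Note the published
¥87.10/QALY differs in the last digit from its own inputs
(470.37/5.40 = 87.106).

One-way sensitivity analysis perturbs one parameter with the rest fixed.
A "10%" change in the control probability is applied as ±10 percentage
points by default — that choice reproduces the published death counts at
28 cycles exactly (57 and 52; a relative ×0.9/×1.1 gives 56 and 53) —
with a relative mode also available.  Out-of-range probabilities are clipped with
a warning.  Probabilistic sensitivity analysis and age-varying hazards
are out of scope.

## Numerical and testing choices

- Everything stochastic is driven by seeded `numpy` generators; cohorts
  are byte-identical for a fixed config.
- Percentages printed to two decimals use decimal half-up rounding to
  match the published figures.
- Tests freeze oracle values (F/χ² quantiles, eigen-decompositions,
  hand covariance arithmetic) computed independently of the code paths
  they check; scikit-learn serves only as the PLS1/PCA cross-check.
- Problem sizes in tests (20-seed recovery/null batches, 200-replicate
  null calibration of the T² ellipse, hypothesis property suites on the
  Markov engine) were chosen to keep the full suite under a minute while
  leaving Monte-Carlo margins comfortably wide.
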