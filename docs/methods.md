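# Methods

This note documents the models, algorithms and design choices behind
`glucodss`: what is simulated, what is fitted, which knobs matter, and what
the in-silico results do and do not show about real-world use.

## The glucoregulatory model

The virtual patient and the titrator's fitting model are the same
continuous-time system: a Bergman-style minimal model (glucose
effectiveness `S_G` [1/min], remote insulin action `X` driven by insulin
sensitivity `S_I` [1/min per mU/L] through a first-order filter with rate
`p2`), a two-compartment gut chain with time constant `τ_m` converting
carbohydrate grams to glucose appearance (molar mass 180.16 g/mol, scaled
by a per-meal-type bioavailability `f_m ∈ (0,1]`), and a two-compartment
subcutaneous depot (`τ_I`) feeding plasma insulin (volume `V_I`,
elimination `k_e`).  The once-daily long-acting basal dose `B` (U/day)
enters as a constant plasma contribution `k_b·B`, appropriate for
degludec/glargine at steady state; no intra-day basal profile is modelled.
Brand-specific PK differences are out of scope: all rapid analogs share
one kinetic profile, all long-acting analogs another.

The fasting equilibrium `G_ss = S_G·G_b/(S_G + S_I·k_b·B)` is decreasing
in `B` and inverts to the closed-form basal requirement
`B* = S_G(G_b − target)/(S_I·k_b·target)`, which doubles as an independent
oracle for titration convergence tests.

Numerics: classical RK4 at a fixed 1-minute step for truth simulation and
5 minutes for fit/replay loops (1- vs 0.25-minute grids agree to well
under 0.05 mmol/L sup-norm; event impulses are aligned to the grid).
Remote action is clamped to [0, 0.4] min⁻¹ — an order of magnitude above
any plausible value — purely to keep the fixed-step scheme stable at the
extreme parameter corners an optimizer may probe.  Glucose is floored at
zero; boluses are impulses into the depot, meals into the gut chain.

Default population parameters (log-normal inter-patient variability where
noted): `S_I` median 6.0e-4 (log-sd 0.35), `G_b` median 15.6 mmol/L
(log-sd 0.42), `k_b` median 0.9 (log-sd 0.20), `f_m` uniform on
[0.75, 0.95]; fixed kinetics `S_G = 0.012`, `p2 = 0.02`, `τ_I = 55`,
`k_e = 0.12`, `V_I = 12 L`, `τ_m = 40`, `V_G = 13 L`.  Only
(S_I, G_b, k_b, f_b, f_l, f_d) are fitted weekly; the kinetics are frozen
at population values because sparse intermittently-scanned CGM cannot
identify them jointly with the sensitivities.

## CGM observation

Historic records every 15 minutes plus scan records at bolus times.
Sensor error is stationary AR(1) Gaussian noise (marginal sd 0.4 mmol/L,
correlation 0.5 at 15-minute lag), clamped to the 2.2–27.8 mmol/L
reporting range.  An optional negative bias below 5 mmol/L is available to
emulate the tendency of intermittently scanned sensors to over-report
hypoglycemia exposure; it defaults to zero and is not used in the shipped
results.  Inside the trial the dosing decision and the stored record share
one noise path, so the diary and the CGM file are mutually consistent.

## Bolus calculator

Food dose `carbs/CR_m` (or the fixed per-meal dose), plus a correction
`(trend-adjusted glucose − target)/ISF`.  Trend arrows add ±1.4 / ±2.8
mmol/L to the scanned value before the correction — common clinical
guidance; the offsets are configurable constants.  Insulin-on-board decays
linearly over the active insulin time (an exponential variant is available
behind a flag) and is subtracted only from the positive correction
component: a large IOB can cancel a correction but never eats into the
food dose of a meal bolus, while a standalone correction is offset in
full.  Negative corrections (glucose below target) may reduce a meal dose
but the total never goes below zero.  Doses round to the pen increment
with ties going *down* — the hypoglycemia-conservative direction.
Override reasons are annotations only and never enter any computation.
Meal-type defaults by clock time (05–11, 11–16, 16–21, else bedtime), the
30-minute entry deletion window, and the adherence alerts (three
consecutive missed basal logs; three or fewer entries in 36 h) follow the
deployed app's stated behaviour.

## Weekly titration

Each week the engine fits φ = (S_I, G_b, k_b, f_b, f_l, f_d) by MAP:
Gaussian likelihood of the historic-record residuals (assumed residual sd
`σ_cgm = 0.5` mmol/L by default — deliberately larger than the sensor
noise to absorb unlogged-meal misfit) plus independent log-normal priors,
optimized by L-BFGS-B in log space from the prior median (initial prior
sds: 0.4, 0.20, 0.35, 0.25, 0.25, 0.25).  Posterior sds come from the
numerical Hessian at the MAP (Laplace); a non-positive-definite Hessian
falls back to the prior sd, i.e. zero confidence.  Fixed-dose users log no
carbohydrate amounts, so their meals are assigned nominal grams
(45/60/70 g for breakfast/lunch/dinner); only the product `f_m · grams`
enters the model, so the fitted `f_m` absorbs the nominal-grams scale.

The optimal therapy sets basal to the closed-form fasting solution at the
MAP and finds each prandial parameter by bounded coordinate descent
(iterated to a joint fixed point) on the replayed-week cost
`J = mean(4·max(0, 3.9−G)² + max(0, G−10)²)`, with a tiny quadratic anchor
toward the incumbent parameter that resolves the indeterminacy when the
whole basin has `J = 0` (glucose entirely in band → "no change" is
selected).  The 4× hypoglycemia weight and the 3.9–10 band are
conventions; they are configuration, not claims.

Blending: per therapy parameter, `w = max(0, R²) · s`, where `s` is the
Laplace shrinkage `clip(1 − (σ_post/σ_prior)², 0, 1)` of the model
parameters that inform it — basal takes the minimum over (S_I, G_b, k_b),
meal `m` the minimum over (S_I, f_m); the minimum is the conservative
choice among reasonable aggregations.  Mixing is in log scale (weight 1/2
gives the geometric mean) and exact at the w = 0 / w = 1 limits.

Safety rule ("trending low"): for each meal type, if any 4-hour
postprandial window after one of its logged boluses that week has a sensor
nadir below 4.5 mmol/L (any reading below 3.9 is a fortiori below that),
the meal's insulin may not increase — the carb ratio may not decrease and
the fixed dose may not increase; overnight (23:00–07:00) readings below
3.9 mmol/L block a basal increase.  Decreases always pass.

Finalization clips every parameter to ±20 % of its predecessor per week —
measured on the insulin-equivalent scale (1/CR for ratios, so "+30 %
insulin" means the same thing for ratios and fixed doses) — then rounds to
the pen increment choosing the nearest multiple *inside* the cap window,
and flags the recommendation when any parameter's cumulative change from
the reference (baseline, or the last flagged-and-approved prescription)
exceeds 30 %.  Flagged recommendations are held until approved; in-silico
runs auto-approve by default.  ISF and the glucose target are never
titrated.  Bedtime boluses exist in the calculator but have no titrated
parameter.

The posterior rolls forward as the next week's prior: median ← MAP, sd ←
min(posterior sd × 1.25, initial sd).  The 1.25 forgetting factor prevents
confidence lock-in while still accumulating information across weeks.
A week with under two days of CGM or no logged bolus takes the degraded
path: a "no change" recommendation with the failure recorded.

## Synthetic cohort and trial

Each virtual participant gets physiology from the population above, a
sensor-use stratum (76 % regular users), a meal strategy (60 % carb
counting), pen increments matching the cohort mix, and an *initial*
therapy derived from their own model-implied oracle (closed-form basal;
prandial intensity from an insulin-vs-carb balance approximation) but
mis-specified: one shared per-participant log-bias drawn from
N(−0.85, 0.90²) times per-parameter log-normal error (sd 0.25).  The
strong, heterogeneous under-dosing is what makes this a suboptimally
controlled cohort; a symmetric per-parameter error alone cannot produce
the intended baseline distribution once the inclusion threshold truncates
it.  Candidates are burned in for 14 days under their initial therapy and
rejected unless the GMI estimate of mean glucose is ≥ 7.5 %; the frozen
calibration places the accepted cohort at mean ≈ 8.6 %, SD ≈ 1.0 %.

Behaviour: three daily meals at jittered times with log-normal sizes;
each meal is bolused through the app with a per-participant Beta
probability (cohort median ≈ 0.90, giving ≈ 2.7 prandial uses/day);
unlogged meals are *eaten but not bolused* — a missed dose, the main
behavioural driver of residual hyperglycemia; basal is injected every day
but logged with probability median ≈ 0.92; correction attempts follow a
per-participant log-normal daily rate (median 0.56); about 8 % of computed
doses are overridden by a factor in [0.7, 1.3], annotated with a reason.
Carb-counting users log true gram amounts (estimation error would be
absorbed by `f_m` exactly like the nominal-grams convention).

The trial randomizes 1:1 with stratified permuted blocks (10 for regular
users, 4 for new users).  Incomplete trailing blocks allow small overall
imbalance, so the runner redraws the sequence until the allocation is
exactly balanced — emulating a coordinator preparing envelopes for the
target per-arm enrollment; the pure block properties remain available and
tested.  Both arms use the bolus calculator; only the experimental arm
receives the weekly recommendation, applied the following week.  The
control arm's parameters stay fixed (the sparse self-initiated changes of
standard care are not simulated — only their count is known, not their
size — and the default leaves them off).  Dropouts, site effects and
concurrent personal CGM are not simulated.

## What the in-silico results mean

The synthetic cohort reproduces targeted *marginals* (baseline estimated
HbA1c distribution, app-use rates); it does not model meal-content
misreporting beyond `f_m`, exercise, stress, alcohol, sensor dropout, or
behaviour change over time.  Because simulated participants apply every
approved recommendation and their physiology is stationary, the between-arm
contrast in silico is much larger than any real-world effect; it is
reported as a directional property (titrated arm ends lower), never as a
reproduction of a clinical effect size.  The HbA1c surrogate is the GMI
regression from mean sensor glucose — an in-silico stand-in, not an assay.

## Problem sizes and runtimes

Truth simulation runs at 1-minute resolution (compiled kernel); weekly
fits replay at 5-minute resolution with an optimizer budget of 400
evaluations.  The default 84-participant, 12-week trial (504 weekly fits)
completes in well under a minute on one core; cohort generation with
burn-ins takes a few seconds.  The acceptance script and the test-suite
audits use these same sizes.

## Known limitations

* The model is one defensible embodiment of a glucoregulatory fitting
  backbone; equivalence with any deployed system's internal model is not
  claimed.  The titration logic is deliberately agnostic to swapping it.
* Identifiability: `S_I` and `k_b` are separated only by the contrast
  between bolus-driven and basal-driven insulin exposure; weeks with few
  logged boluses shrink toward the prior (by design).
* The 30 % review rule is applied per parameter on the insulin-equivalent
  scale; whether a deployed system compares raw ratios instead is an open
  choice documented here.
* Wald intervals are used for proportion differences; exact-test p-values
  and chi-squared tests are reported as defined, with no tuning toward any
  externally printed value.
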