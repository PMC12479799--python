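# glucodss

Decision support for basal–bolus (multiple-daily-injection, MDI) insulin
therapy in type 1 diabetes, together with the machinery to evaluate it in a
seeded in-silico randomized trial.  The package is aimed at researchers in
glycemic-control algorithms who want a transparent, fully testable
re-implementation of a weekly insulin-titration decision support system:
a bolus calculator, a glucose–insulin simulation model, a Bayesian weekly
titration engine with safety and review rules, CGM endpoint analytics, and
a virtual-patient trial runner.

## What it computes

**Bolus calculator.**  For a meal with `c` grams of carbohydrate at sensor
glucose `G` with trend arrow `a`:

    dose = max(0, c/CR_m + [(G + offset(a) − G_target)/ISF]_+ − IOB + [(G + offset(a) − G_target)/ISF]_−)

where `CR_m` is the meal-specific carbohydrate ratio (g/U; or a fixed
per-meal dose), `ISF` the insulin sensitivity factor (mmol/L per U), and
IOB the insulin-on-board, a linear decay of recent rapid-acting boluses
over the active insulin time.  IOB is only subtracted from the positive
correction part, never from the food dose; results are rounded to the pen
increment (ties down).

**Glucoregulatory model.**  A minimal-model core with two-compartment gut
absorption and subcutaneous rapid-insulin kinetics:

    S1' = −S1/τ_I,  S2' = (S1−S2)/τ_I,  I' = S2/(τ_I·V_I) − k_e·I
    X'  = −p2·X + p2·S_I·(I + k_b·B)
    Q1' = −Q1/τ_m,  Q2' = (Q1−Q2)/τ_m
    G'  = −(S_G + X)·G + S_G·G_b + Q2/(τ_m·V_G)

with once-daily basal `B` (U/day) as a constant plasma contribution
`k_b·B`.  The fasting equilibrium is `G_ss = S_G·G_b/(S_G + S_I·k_b·B)`,
invertible in closed form for the basal that holds any fasting target.

**Weekly titration.**  Each week, φ = (S_I, G_b, k_b, f_breakfast,
f_lunch, f_dinner) is fitted by MAP with log-normal priors (Laplace
posterior sds from the numerical Hessian); the optimal therapy replays the
week under candidate parameters minimizing a band cost (quadratic
penalties outside 3.9–10 mmol/L, hypoglycemia weighted 4×); the
recommendation is a log-scale mixture of optimum and incumbent with weight
`w = max(0,R²)·clip(1−(σ_post/σ_prior)², 0, 1)`, attenuated one-sidedly
when postprandial windows trended low (< 4.5 mmol/L nadir) or overnight
glucose fell below 3.9, capped at ±20 % per week, rounded to pen
increments, and flagged for clinician review when any parameter moves
more than 30 % cumulatively from the last approved prescription.

**Trial analytics.**  Consensus CGM time-in-range metrics, the GMI
estimated HbA1c (3.31 + 0.02392 · mean glucose in mg/dL), baseline-adjusted
treatment effects (ANCOVA), exact and chi-squared proportion tests,
normality-gated two-group comparisons, and noncentral-t sample-size
calculation.

## Worked example

`examples/weekly_titration.py` titrates a patient whose true basal
requirement is 50.3 U/day starting from 30 U with weak carb ratios:

```
true basal requirement: 50.3 U/day; starting at 30 U
week 0: basal  36.0 U, CR 12.0/10.0/10.5 g/U, flagged=False
week 1: basal  43.0 U, CR 12.0/9.9/10.5 g/U, flagged=True
week 2: basal  46.0 U, CR 12.0/9.8/10.5 g/U, flagged=False
...
week 5: basal  50.0 U, CR 12.0/9.8/10.5 g/U, flagged=False
```

Each step respects the 20 % weekly cap; the week-1 move is flagged because
the cumulative change from baseline exceeded 30 % and would require
clinician approval before transmission.  `examples/run_small_trial.py`
runs a reduced 16-participant, 6-week trial and prints the between-arm
estimated-HbA1c effect; the other examples cover the bolus calculator,
forward simulation with CGM observation, and the endpoint statistics.

A thin CLI mirrors the library: `glucodss bolus|metrics|titrate|simulate|
trial|analyze` (see `glucodss --help`).

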