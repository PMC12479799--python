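"""Weekly Bayesian titration closing in on an under-insulinized patient.

The patient's true basal requirement is ~50 U/day but they start at 60% of
that with too-weak carb ratios.  Each week the engine fits the model to the
week's (noiseless, fully logged) data, proposes the optimal therapy, blends
it by confidence, and caps the move at 20%; basal walks up to the
closed-form requirement within a few weeks.
"""

from glucodss import (
    TherapyParameters,
    TitrationState,
    build_logged_week,
    steady_state_basal,
    titrate_week,
)
from glucodss.config import default_config

base = default_config().population.base_physiology()
truth = base.with_fitted(
    S_I=base.S_I * 0.8, G_b=base.G_b * 1.15, k_b=base.k_b * 1.1,
    f={"breakfast": 0.9, "lunch": 0.8, "dinner": 0.85},
)
target_basal = steady_state_basal(truth, 6.0)
therapy = TherapyParameters(
    basal_dose=round(0.6 * target_basal), meal_strategy="carb_counting",
    carb_ratio={"breakfast": 12.0, "lunch": 12.0, "dinner": 12.0},
    glucose_target=6.0,
)
state = TitrationState.initial(therapy, base)
print(f"true basal requirement: {target_basal:.1f} U/day; starting at {therapy.basal_dose:.0f} U")
for week_idx in range(8):
    week = build_logged_week(truth, therapy, noise_sd=0.0, week=week_idx)
    rec, state = titrate_week(week, therapy, state, base)
    therapy = rec.therapy
    cr = therapy.carb_ratio
    print(f"week {week_idx}: basal {therapy.basal_dose:5.1f} U, "
          f"CR {cr['breakfast']:.1f}/{cr['lunch']:.1f}/{cr['dinner']:.1f} g/U, "
          f"flagged={rec.flagged}")
print("each step stays within the 20% weekly cap; >30% cumulative moves were "
      "flagged for review before transmission")
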