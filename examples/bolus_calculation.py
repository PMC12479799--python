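"""Meal and correction bolus doses with insulin-on-board accounting.

A carb-counting user scans 10.0 mmol/L (stable) before a 60 g dinner, two
hours after a 2 U lunch-time bolus.  The calculator covers the carbs
(60 g / CR 10 = 6 U), adds a correction toward target, and subtracts the
still-active insulin from the correction only.
"""

from glucodss import TherapyParameters, meal_bolus, correction_bolus
from glucodss.events import DoseEvent, EventKind

therapy = TherapyParameters(
    basal_dose=20.0,
    meal_strategy="carb_counting",
    carb_ratio={"breakfast": 10.0, "lunch": 10.0, "dinner": 10.0},
    isf=2.0,                 # 1 U drops ~2 mmol/L
    glucose_target=5.5,      # mmol/L
    active_insulin_time=4.0,  # hours
    bolus_increment=0.5,
)

earlier_bolus = DoseEvent(timestamp=0.0, kind=EventKind.meal_bolus, delivered=2.0)
now = 120.0  # two hours later -> 1.0 U still on board

dose, detail = meal_bolus(
    therapy, "dinner", carbs=60, glucose=10.0, arrow="stable",
    events=[earlier_bolus], now=now,
)
print(f"meal bolus: {dose:.1f} U")
print(f"  food {detail.food:.2f} U + correction {detail.correction:+.2f} U "
      f"- IOB applied {detail.iob_applied:.2f} U -> raw {detail.raw_total:.2f} U, "
      f"rounded to the 0.5-U pen")

dose, detail = correction_bolus(therapy, glucose=14.0, arrow="rising",
                                events=[], now=now)
print(f"standalone correction at 14.0 mmol/L rising: {dose:.1f} U "
      f"(trend-adjusted glucose 15.4, correction {detail.correction:.2f} U)")
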