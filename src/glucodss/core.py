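"""Core therapy types shared by the calculator, titrator and trial engine.

A multiple-daily-injection (MDI) prescription consists of a once-daily
long-acting basal dose plus rapid-acting prandial doses at meals, computed
either from a per-meal carbohydrate ratio (grams covered per unit) or as a
fixed per-meal dose.  Insulin pens deliver in discrete increments, so every
recommended dose is rounded to the pen's step.

Glucose is handled internally in mmol/L; ``MGDL_PER_MMOLL`` converts to
mg/dL where needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum

MGDL_PER_MMOLL = 18.016

BASAL_INCREMENTS = (0.5, 1.0, 2.0)
BOLUS_INCREMENTS = (0.5, 1.0)

#: Prandial meal slots that carry a titratable parameter.  A "bedtime" meal
#: type exists in the calculator but has no titrated parameter.
MEALS = ("breakfast", "lunch", "dinner")


class MealStrategy(str, Enum):
    carb_counting = "carb_counting"
    fixed_dose = "fixed_dose"


class InvalidArgument(ValueError):
    """Raised when an operation precondition is violated."""


def round_to_increment(dose: float, increment: float) -> float:
    """Round ``dose`` to the nearest multiple of a pen ``increment``.

    Exact ties round *down*: when a computed dose falls exactly between two
    deliverable doses the smaller one is chosen (hypoglycemia-conservative).
    """
    if not math.isfinite(dose) or dose < 0:
        raise InvalidArgument(f"dose must be finite and >= 0, got {dose!r}")
    if increment not in BASAL_INCREMENTS:
        raise InvalidArgument(
            f"increment must be one of {BASAL_INCREMENTS}, got {increment!r}"
        )
    q = dose / increment
    frac = q - math.floor(q)
    # tie detection is tolerant of float representation of e.g. 8.25/0.5
    if abs(frac - 0.5) <= 1e-9 * max(1.0, abs(q)):
        k = math.floor(q)
    else:
        k = math.floor(q + 0.5)
    return max(0.0, k * increment)


def cumulative_change(value: float, reference: float) -> float:
    """Signed relative change of ``value`` from a reference dose.

    Returns ``value/reference - 1``; the 30% review rule compares the
    absolute value of this quantity against its threshold.
    """
    if not reference > 0:
        raise InvalidArgument(f"reference must be > 0, got {reference!r}")
    return value / reference - 1.0


@dataclass
class TherapyParameters:
    """The titratable MDI prescription plus fixed calculator settings.

    Exactly one of ``carb_ratio`` / ``fixed_dose`` is populated, according to
    the locked ``meal_strategy``.  ``isf`` (insulin sensitivity factor,
    mmol/L dropped per unit), ``glucose_target`` and ``active_insulin_time``
    are used by the bolus calculator but are never titrated.
    """

    basal_dose: float
    meal_strategy: MealStrategy
    carb_ratio: dict[str, float] | None = None  # grams per unit
    fixed_dose: dict[str, float] | None = None  # units
    isf: float = 2.0
    glucose_target: float = 6.0
    active_insulin_time: float = 4.0  # hours
    basal_increment: float = 1.0
    bolus_increment: float = 0.5

    def __post_init__(self) -> None:
        self.meal_strategy = MealStrategy(self.meal_strategy)
        if self.basal_dose < 0:
            raise InvalidArgument("basal_dose must be >= 0")
        if self.isf <= 0 or self.glucose_target <= 0:
            raise InvalidArgument("isf and glucose_target must be > 0")
        if self.active_insulin_time <= 0:
            raise InvalidArgument("active_insulin_time must be > 0")
        if self.basal_increment not in BASAL_INCREMENTS:
            raise InvalidArgument(f"basal_increment must be in {BASAL_INCREMENTS}")
        if self.bolus_increment not in BOLUS_INCREMENTS:
            raise InvalidArgument(f"bolus_increment must be in {BOLUS_INCREMENTS}")
        if self.meal_strategy is MealStrategy.carb_counting:
            if self.carb_ratio is None or self.fixed_dose is not None:
                raise InvalidArgument(
                    "carb_counting therapy must set carb_ratio and not fixed_dose"
                )
            if set(self.carb_ratio) != set(MEALS):
                raise InvalidArgument(f"carb_ratio must cover meals {MEALS}")
            if any(v <= 0 for v in self.carb_ratio.values()):
                raise InvalidArgument("carb ratios must be > 0")
        else:
            if self.fixed_dose is None or self.carb_ratio is not None:
                raise InvalidArgument(
                    "fixed_dose therapy must set fixed_dose and not carb_ratio"
                )
            if set(self.fixed_dose) != set(MEALS):
                raise InvalidArgument(f"fixed_dose must cover meals {MEALS}")
            if any(v < 0 for v in self.fixed_dose.values()):
                raise InvalidArgument("fixed doses must be >= 0")

    # -- insulin-equivalent view -------------------------------------------
    # Carb-ratio changes are tracked as relative change of the implied
    # dose-per-gram (1/CR) so that "+30% insulin" flags symmetrically for
    # ratios and fixed doses.

    def prandial_insulin_equivalent(self, meal: str) -> float:
        """Insulin intensity for a meal: units for fixed dose, 1/CR for CC."""
        if self.meal_strategy is MealStrategy.carb_counting:
            return 1.0 / self.carb_ratio[meal]
        return self.fixed_dose[meal]

    def with_prandial(self, meal: str, insulin_equivalent: float) -> "TherapyParameters":
        """Copy with one meal's insulin intensity replaced (same scale as
        :meth:`prandial_insulin_equivalent`)."""
        if insulin_equivalent <= 0:
            raise InvalidArgument("prandial insulin equivalent must be > 0")
        if self.meal_strategy is MealStrategy.carb_counting:
            cr = dict(self.carb_ratio)
            cr[meal] = 1.0 / insulin_equivalent
            return replace(self, carb_ratio=cr)
        fd = dict(self.fixed_dose)
        fd[meal] = insulin_equivalent
        return replace(self, fixed_dose=fd)

    def with_basal(self, basal_dose: float) -> "TherapyParameters":
        return replace(self, basal_dose=basal_dose)

    def titratable(self) -> dict[str, float]:
        """All titratable parameters on the insulin-equivalent scale."""
        out = {"basal": self.basal_dose}
        for m in MEALS:
            out[m] = self.prandial_insulin_equivalent(m)
        return out


@dataclass
class ParameterChange:
    """Accounting record for one titrated parameter across a recommendation."""

    parameter: str
    previous: float
    new: float
    relative_change: float = field(init=False)
    cumulative_from_reference: float = 0.0
    flagged: bool = False

    def __post_init__(self) -> None:
        self.relative_change = cumulative_change(self.new, self.previous)


def parameter_changes(
    new: TherapyParameters,
    previous: TherapyParameters,
    reference: TherapyParameters,
    review_threshold: float = 0.30,
) -> list[ParameterChange]:
    """Per-parameter change records on the insulin-equivalent scale.

    ``flagged`` is set iff the cumulative change from the reference therapy
    (baseline or last clinician-approved prescription) exceeds the review
    threshold in absolute value.
    """
    out = []
    new_t, prev_t, ref_t = new.titratable(), previous.titratable(), reference.titratable()
    for name in new_t:
        cum = cumulative_change(new_t[name], ref_t[name])
        out.append(
            ParameterChange(
                parameter=name,
                previous=prev_t[name],
                new=new_t[name],
                cumulative_from_reference=cum,
                # strictly "more than"; tolerant of float representation
                flagged=abs(cum) > review_threshold * (1 + 1e-9),
            )
        )
    return out
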