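"""Real-time meal and correction bolus calculator.

Doses are computed from the programmed therapy parameters, the scanned
sensor glucose and its trend arrow, with undissipated rapid-acting insulin
(insulin on board, IOB) subtracted to prevent stacking.  The IOB decay is
linear over the active insulin time by default; a single-exponential decay
with the same time scale is available via ``decay="exponential"``.

Trend arrows adjust the effective glucose before the correction term is
formed; the offsets follow common clinical guidance for 15-minute trend
arrows (the glucose expected to be gained or lost over the insulin's onset).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .core import InvalidArgument, MealStrategy, TherapyParameters, round_to_increment
from .events import DoseEvent, EventKind, EventLog, TrendArrow

#: mmol/L added to the scanned glucose per trend arrow.
TREND_OFFSETS: dict[TrendArrow, float] = {
    TrendArrow.rising_fast: 2.8,
    TrendArrow.rising: 1.4,
    TrendArrow.stable: 0.0,
    TrendArrow.falling: -1.4,
    TrendArrow.falling_fast: -2.8,
}

GLUCOSE_FLOOR = 0.1

#: Default meal-type windows by local clock hour (inclusive start).
MEAL_WINDOWS = {"breakfast": (5, 11), "lunch": (11, 16), "dinner": (16, 21)}

MISSED_BASAL_STREAK = 3
INSUFFICIENT_USE_MAX_ENTRIES = 3
INSUFFICIENT_USE_WINDOW_MIN = 36 * 60.0


class MissingGlucose(InvalidArgument):
    """The app refuses to compute a dose without a sensor scan."""


def insulin_on_board(
    events: EventLog | list[DoseEvent],
    now: float,
    active_insulin_time: float,
    decay: str = "linear",
) -> float:
    """Undissipated rapid-acting insulin at ``now`` (units).

    Only meal and correction boluses contribute; basal injections are
    long-acting and excluded.  Each dose decays linearly to zero over
    ``active_insulin_time`` hours (or exponentially with mean residence
    equal to half the active insulin time when ``decay="exponential"``).
    """
    if active_insulin_time <= 0:
        raise InvalidArgument("active_insulin_time must be > 0")
    ait_min = active_insulin_time * 60.0
    total = 0.0
    for ev in events:
        if ev.kind not in (EventKind.meal_bolus, EventKind.correction_bolus):
            continue
        elapsed = now - ev.timestamp
        if elapsed < 0:
            continue
        if decay == "linear":
            total += ev.delivered * max(0.0, 1.0 - elapsed / ait_min)
        elif decay == "exponential":
            total += ev.delivered * math.exp(-2.0 * elapsed / ait_min)
        else:
            raise InvalidArgument(f"unknown decay {decay!r}")
    return total


def trend_adjusted_glucose(glucose: float, arrow: TrendArrow | str) -> float:
    """Scanned glucose shifted by the trend-arrow offset, floored at 0.1."""
    if glucose <= 0:
        raise InvalidArgument("glucose must be > 0")
    try:
        arrow = TrendArrow(arrow)
    except ValueError as exc:
        raise InvalidArgument(f"unknown trend arrow {arrow!r}") from exc
    return max(GLUCOSE_FLOOR, glucose + TREND_OFFSETS[arrow])


@dataclass
class BolusBreakdown:
    """Calculation details retained with each recommendation."""

    food: float
    correction: float
    iob: float
    iob_applied: float
    raw_total: float
    rounded: float


def _correction_units(
    therapy: TherapyParameters, glucose: float, arrow: TrendArrow | str
) -> float:
    return (trend_adjusted_glucose(glucose, arrow) - therapy.glucose_target) / therapy.isf


def meal_bolus(
    therapy: TherapyParameters,
    meal: str,
    carbs: float | None,
    glucose: float | None,
    arrow: TrendArrow | str,
    events: EventLog | list[DoseEvent],
    now: float,
    decay: str = "linear",
) -> tuple[float, BolusBreakdown]:
    """Recommended meal dose (units) and its breakdown.

    The food component is ``carbs / CR[meal]`` (carb counting) or the fixed
    per-meal dose.  The correction component may be negative (glucose below
    target reduces the meal dose) but IOB is only ever subtracted from the
    *positive* part of the correction — it never eats into the food dose.
    The total is clipped at zero and rounded to the bolus pen increment.
    """
    if glucose is None:
        raise MissingGlucose("a sensor glucose scan is required to compute a bolus")
    if therapy.meal_strategy is MealStrategy.carb_counting:
        if carbs is None or carbs < 0:
            raise InvalidArgument("carb_counting therapy requires carbs >= 0")
        food = carbs / therapy.carb_ratio[meal]
    else:
        food = therapy.fixed_dose[meal]
    correction = _correction_units(therapy, glucose, arrow)
    iob = insulin_on_board(events, now, therapy.active_insulin_time, decay)
    corr_pos = max(0.0, correction)
    corr_neg = min(0.0, correction)
    iob_applied = min(iob, corr_pos)
    raw = max(0.0, food + (corr_pos - iob_applied) + corr_neg)
    rounded = round_to_increment(raw, therapy.bolus_increment)
    return rounded, BolusBreakdown(food, correction, iob, iob_applied, raw, rounded)


def correction_bolus(
    therapy: TherapyParameters,
    glucose: float | None,
    arrow: TrendArrow | str,
    events: EventLog | list[DoseEvent],
    now: float,
    decay: str = "linear",
) -> tuple[float, BolusBreakdown]:
    """Standalone correction dose: ``max(0, correction - IOB)``, rounded."""
    if glucose is None:
        raise MissingGlucose("a sensor glucose scan is required to compute a bolus")
    correction = _correction_units(therapy, glucose, arrow)
    iob = insulin_on_board(events, now, therapy.active_insulin_time, decay)
    raw = max(0.0, correction - iob)
    rounded = round_to_increment(raw, therapy.bolus_increment)
    return rounded, BolusBreakdown(0.0, correction, iob, min(iob, max(correction, 0.0)), raw, rounded)


def default_meal_type(clock_hour: float) -> str:
    """Default meal slot by local time of day (user may override).

    Breakfast 05:00-10:59, lunch 11:00-15:59, dinner 16:00-20:59, bedtime
    otherwise.
    """
    if not 0 <= clock_hour < 24:
        raise InvalidArgument("clock_hour must be in [0, 24)")
    for meal, (lo, hi) in MEAL_WINDOWS.items():
        if lo <= clock_hour < hi:
            return meal
    return "bedtime"


@dataclass
class AlertState:
    """Adherence alerts shown by the app."""

    missed_basal_streak: int
    entries_last_36h: int

    @property
    def missed_basal_alert(self) -> bool:
        return self.missed_basal_streak >= MISSED_BASAL_STREAK

    @property
    def insufficient_use_alert(self) -> bool:
        return self.entries_last_36h <= INSUFFICIENT_USE_MAX_ENTRIES

    @property
    def active_alerts(self) -> set[str]:
        out = set()
        if self.missed_basal_alert:
            out.add("missed_basal")
        if self.insufficient_use_alert:
            out.add("insufficient_use")
        return out


def update_alerts(log: EventLog, now: float) -> AlertState:
    """Recompute adherence alerts at ``now``.

    The missed-basal streak counts consecutive completed calendar days
    immediately before ``now`` with no basal log; the alert fires at three.
    Insufficient use means three or fewer log entries in the trailing 36 h.
    """
    day = math.floor(now / 1440.0)
    basal_days = {
        math.floor(ev.timestamp / 1440.0) for ev in log.of_kind(EventKind.basal)
    }
    streak = 0
    d = day - 1
    while d >= 0 and d not in basal_days:
        streak += 1
        d -= 1
    entries = len(log.between(now - INSUFFICIENT_USE_WINDOW_MIN, now + 1e-9))
    return AlertState(missed_basal_streak=streak, entries_last_36h=entries)
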