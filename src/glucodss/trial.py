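"""In-silico randomized trial engine.

Simulates each participant minute-by-minute: meals are eaten on a jittered
daily schedule, app-logged meals receive a calculator bolus computed from
the (noisy) sensor glucose and trend arrow, unlogged meals are eaten
without a bolus, basal is injected daily (logged or not), and occasional
correction boluses are taken.  The experimental arm additionally receives
the weekly titration engine's recommendation, applied the following week;
the control arm keeps its initial parameters throughout (the standard-care
app without the adaptive algorithm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import kernels
from .bolus import correction_bolus, meal_bolus
from .cohort import VirtualParticipant, sample_participant, permuted_block_randomize
from .config import RunConfig, default_config
from .core import MEALS, MealStrategy, TherapyParameters, round_to_increment
from .events import DoseEvent, EventKind, EventLog, OverrideReason
from .model import (
    MINUTES_PER_DAY,
    MMOL_PER_GRAM,
    CgmTrace,
    PatientPhysiology,
    SensorModel,
    arrow_from_slope,
    initial_fasting_state,
    observe_cgm,
)
from .outcomes import cgm_metrics, estimate_hba1c
from .titration import Recommendation, TitrationState, WeekData, titrate_week

BURN_IN_DAYS = 14

_EMPTY_I = np.empty(0, dtype=np.int64)
_EMPTY_F = np.empty(0, dtype=float)

OVERRIDE_REASONS = [r for r in OverrideReason if r is not OverrideReason.none]


class CalibrationError(RuntimeError):
    """Cohort rejection sampling stalled; calibration is inconsistent."""


@dataclass
class _DayEvent:
    minute: float  # absolute minutes
    kind: str  # "meal" | "correction" | "basal_log"
    grams: float = 0.0
    meal_type: str = ""
    logged: bool = True


def _plan_day(
    day: int,
    participant: VirtualParticipant,
    cfg: RunConfig,
    rng: np.random.Generator,
) -> list[_DayEvent]:
    t0 = day * MINUTES_PER_DAY
    plan: list[_DayEvent] = []
    meals_cfg = cfg.meals
    for m in MEALS:
        minute = meals_cfg.times_h[m] * 60.0 + rng.normal(0, meals_cfg.time_jitter_min)
        minute = float(np.clip(minute, 5 * 60.0, 22 * 60.0))
        grams = meals_cfg.grams_median[m] * math.exp(
            rng.normal(0, meals_cfg.grams_log_sd)
        )
        plan.append(
            _DayEvent(
                minute=t0 + round(minute), kind="meal", grams=grams, meal_type=m,
                logged=bool(rng.random() < participant.adherence.p_meal_bolus),
            )
        )
    n_corr = rng.poisson(participant.adherence.correction_rate)
    for _ in range(n_corr):
        minute = float(rng.uniform(9 * 60.0, 22.5 * 60.0))
        plan.append(_DayEvent(minute=t0 + round(minute), kind="correction"))
    plan.append(
        _DayEvent(
            minute=t0 + 21.5 * 60.0, kind="basal_log",
            logged=bool(rng.random() < participant.adherence.p_basal_log),
        )
    )
    plan.sort(key=lambda e: e.minute)
    return plan


def simulate_days(
    participant: VirtualParticipant,
    therapy: TherapyParameters,
    start_day: int,
    n_days: int,
    state: np.ndarray,
    rng: np.random.Generator,
    cfg: RunConfig,
    sensor: SensorModel | None = None,
) -> tuple[np.ndarray, np.ndarray, EventLog, np.ndarray, np.ndarray]:
    """Simulate ``n_days`` of free-living behaviour.

    Returns (times, true glucose on the minute grid, event log, sensor
    noise path, final model state).  Dose decisions inside use the noisy
    sensor value at the decision minute, so the stored event log and the
    CGM record derived from the same noise path are mutually consistent.
    """
    sensor = sensor or cfg.sensor.sensor_model()
    phys = participant.physiology
    p_arr = phys.as_array()
    t0 = start_day * MINUTES_PER_DAY
    n_min = n_days * MINUTES_PER_DAY
    times = t0 + np.arange(n_min + 1, dtype=float)
    glucose = np.empty(n_min + 1)
    glucose[0] = state[6]
    noise = sensor.noise_path(n_min + 1, rng)
    log = EventLog()
    carb_counting = therapy.meal_strategy is MealStrategy.carb_counting

    events: list[_DayEvent] = []
    for d in range(start_day, start_day + n_days):
        events.extend(_plan_day(d, participant, cfg, rng))

    y = np.asarray(state, dtype=float).copy()
    cursor = 0  # minutes into the period

    def advance(to_minute: int) -> None:
        nonlocal cursor, y
        n = to_minute - cursor
        if n <= 0:
            return
        states = kernels.integrate(
            y, n, 1.0, p_arr, therapy.basal_dose,
            _EMPTY_I, _EMPTY_F, _EMPTY_I, _EMPTY_F,
        )
        glucose[cursor + 1 : to_minute + 1] = states[1:, 6]
        y = states[-1]
        cursor = to_minute

    def sensor_glucose(idx: int) -> float:
        return float(sensor.report(glucose[idx : idx + 1], noise[idx : idx + 1])[0])

    def arrow(idx: int):
        back = max(0, idx - 15)
        if idx == back:
            return arrow_from_slope(0.0)
        return arrow_from_slope(sensor_glucose(idx) - sensor_glucose(back))

    for ev in events:
        idx = int(round(ev.minute - t0))
        if idx >= n_min:
            continue
        advance(idx)
        now = float(ev.minute)
        if ev.kind == "meal":
            delivered = 0.0
            if ev.logged:
                sg = sensor_glucose(idx)
                rec_dose, detail = meal_bolus(
                    therapy, ev.meal_type, ev.grams if carb_counting else None,
                    sg, arrow(idx), log, now,
                )
                delivered = rec_dose
                reason = OverrideReason.none
                if rec_dose > 0 and rng.random() < participant.adherence.p_override:
                    scale = rng.uniform(
                        cfg.adherence.override_scale_low, cfg.adherence.override_scale_high
                    )
                    delivered = round_to_increment(
                        rec_dose * scale, therapy.bolus_increment
                    )
                    if delivered != rec_dose:
                        reason = OVERRIDE_REASONS[rng.integers(len(OVERRIDE_REASONS))]
                log.append(
                    DoseEvent(
                        timestamp=now, kind=EventKind.meal_bolus, delivered=delivered,
                        carbs=ev.grams if carb_counting else None, glucose=sg,
                        arrow=arrow(idx), recommended=rec_dose,
                        override_reason=reason, meal_type=ev.meal_type,
                    )
                )
            # the meal is eaten either way
            y[4] += ev.grams * MMOL_PER_GRAM * phys.bioavailability(ev.meal_type)
            y[0] += delivered * 1000.0
        elif ev.kind == "correction":
            sg = sensor_glucose(idx)
            rec_dose, detail = correction_bolus(therapy, sg, arrow(idx), log, now)
            log.append(
                DoseEvent(
                    timestamp=now, kind=EventKind.correction_bolus,
                    delivered=rec_dose, glucose=sg, arrow=arrow(idx),
                    recommended=rec_dose,
                )
            )
            y[0] += rec_dose * 1000.0
        elif ev.kind == "basal_log" and ev.logged:
            log.append(
                DoseEvent(
                    timestamp=now, kind=EventKind.basal,
                    delivered=therapy.basal_dose,
                )
            )
    advance(n_min)
    return times, glucose, log, noise, y


def build_logged_week(
    phys: PatientPhysiology,
    therapy: TherapyParameters,
    days: int = 7,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    week: int = 0,
) -> WeekData:
    """Deterministic fully-logged week: 3 meals/day, every bolus logged.

    A convenience for titration experiments and oracle tests: the fixed
    schedule is simulated on the titrator's own replay grid, so noiseless
    data are exactly reproducible by the fitting model.  Contrast with
    :func:`simulate_days`, which models realistic partial adherence.
    """
    rng = rng or np.random.default_rng(0)
    meal_plan = [("breakfast", 450, 45.0), ("lunch", 750, 60.0), ("dinner", 1110, 70.0)]
    carb_counting = therapy.meal_strategy is MealStrategy.carb_counting
    meals, boluses, events = [], [], EventLog()
    for d in range(days):
        for mt, minute, grams in meal_plan:
            t = d * MINUTES_PER_DAY + minute
            dose = grams / therapy.carb_ratio[mt] if carb_counting else therapy.fixed_dose[mt]
            meals.append((t, grams, mt))
            boluses.append((t, dose))
            events.append(
                DoseEvent(
                    timestamp=float(t), kind=EventKind.meal_bolus, delivered=dose,
                    carbs=grams if carb_counting else None, meal_type=mt,
                    recommended=dose,
                )
            )
    from .model import simulate

    sim = simulate(phys, therapy.basal_dose, boluses, meals, days, dt=5.0)
    hist_idx = np.arange(0, len(sim.times), 3)  # every 15 min on the 5-min grid
    obs = sim.glucose[hist_idx] + noise_sd * rng.standard_normal(len(hist_idx))
    cgm = CgmTrace(sim.times[hist_idx], obs, np.zeros(len(hist_idx), int))
    return WeekData(cgm=cgm, events=events, week=week)


def burn_in_hba1c(
    participant: VirtualParticipant,
    cfg: RunConfig,
    rng: np.random.Generator,
    days: int = BURN_IN_DAYS,
) -> float:
    """Estimated HbA1c (GMI) over a burn-in under the initial therapy."""
    state = initial_fasting_state(participant.physiology, participant.therapy.basal_dose)
    _, glucose, _, _, _ = simulate_days(
        participant, participant.therapy, 0, days, state, rng, cfg
    )
    return estimate_hba1c(float(glucose.mean()))


def generate_cohort(
    n: int,
    seed: int | np.random.Generator,
    cfg: RunConfig | None = None,
) -> list[VirtualParticipant]:
    """Rejection-sample ``n`` participants meeting the inclusion criterion.

    Candidates are drawn from the documented population; each is given a
    14-day burn-in under the mis-specified initial therapy and kept only if
    the estimated baseline HbA1c is at or above the inclusion threshold
    (7.5%), mirroring the enrolled suboptimally controlled population.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    cfg = cfg or default_config()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: list[VirtualParticipant] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 100 * n:
            raise CalibrationError(
                f"rejection sampling stalled after {attempts} attempts"
            )
        p = sample_participant(len(out), rng, cfg.population, cfg.adherence, cfg.meals)
        a1c = burn_in_hba1c(p, cfg, rng)
        if a1c >= cfg.population.min_baseline_hba1c:
            p.baseline_hba1c = a1c
            out.append(p)
    return out


# ---------------------------------------------------------------------------


@dataclass
class TrialResult:
    """Everything recorded in one in-silico trial run."""

    assignments: dict[int, str]
    weekly: pd.DataFrame  # per participant-week metrics
    therapy_history: pd.DataFrame
    recommendations: list[tuple[int, int, Recommendation]]
    cohort: list[VirtualParticipant]
    weeks: int
    seed: int | None = None

    def arm(self, name: str) -> list[int]:
        return [pid for pid, a in self.assignments.items() if a == name]

    def prandial_uses_per_day(self) -> pd.Series:
        """Mean daily prandial bolus-calculator uses per participant."""
        per = self.weekly.groupby("pid")["n_prandial"].sum() / (self.weeks * 7.0)
        return per

    def basal_logs_per_day(self) -> pd.Series:
        return self.weekly.groupby("pid")["n_basal_logs"].sum() / (self.weeks * 7.0)

    def final_week_mean_glucose(self) -> pd.Series:
        last = self.weekly[self.weekly.week == self.weeks - 1]
        return last.set_index("pid")["mean_true_glucose"]

    def estimated_hba1c_change(self) -> pd.DataFrame:
        """Baseline GMI vs final-week GMI per participant."""
        rows = []
        final = self.final_week_mean_glucose()
        for p in self.cohort:
            rows.append(
                {
                    "pid": p.pid,
                    "arm": self.assignments[p.pid],
                    "baseline": p.baseline_hba1c,
                    "final": estimate_hba1c(final.loc[p.pid]),
                }
            )
        df = pd.DataFrame(rows)
        df["change"] = df["final"] - df["baseline"]
        return df


def _therapy_row(pid: int, week: int, t: TherapyParameters, flagged=False, approved=True):
    tt = t.titratable()
    return {
        "pid": pid, "week": week, "basal_u": t.basal_dose,
        "breakfast": tt["breakfast"], "lunch": tt["lunch"], "dinner": tt["dinner"],
        "strategy": t.meal_strategy.value, "flagged": flagged, "approved": approved,
    }


def run_trial(
    cohort: list[VirtualParticipant],
    weeks: int = 12,
    seed: int = 0,
    cfg: RunConfig | None = None,
    assignments: dict[int, str] | None = None,
) -> TrialResult:
    """Run the two-arm in-silico trial.

    Both arms use the bolus calculator with their current parameters; the
    experimental arm's parameters are retitrated weekly (recommendations
    applied the following week upon acknowledgement).  All weekly metrics,
    therapy trajectories and the recommendation ledger are recorded.
    """
    cfg = cfg or default_config()
    root = np.random.SeedSequence(seed)
    rand_ss, *participant_ss = root.spawn(len(cohort) + 1)
    if assignments is None:
        assignments = permuted_block_randomize(
            cohort, np.random.default_rng(rand_ss), force_balance=True
        )
    sensor = cfg.sensor.sensor_model()
    settings = cfg.titration.settings()
    base_phys = cfg.population.base_physiology()

    weekly_rows = []
    therapy_rows = []
    ledger: list[tuple[int, int, Recommendation]] = []

    for p, ss in zip(cohort, participant_ss):
        rng = np.random.default_rng(ss)
        arm = assignments[p.pid]
        therapy = p.therapy
        state = initial_fasting_state(p.physiology, therapy.basal_dose)
        tstate = TitrationState.initial(therapy, base_phys)
        pending: Recommendation | None = None

        for w in range(weeks):
            if pending is not None and pending.approved:
                therapy = pending.therapy
            pending = None
            therapy_rows.append(_therapy_row(p.pid, w, therapy))

            times, glucose, log, noise, state = simulate_days(
                p, therapy, w * 7, 7, state, rng, cfg, sensor
            )
            scan_times = [
                e.timestamp
                for e in log.of_kind(EventKind.meal_bolus, EventKind.correction_bolus)
            ]
            cgm = observe_cgm(times, glucose, sensor, scan_times, rng, noise=noise)
            m = cgm_metrics(cgm, "overall")
            weekly_rows.append(
                {
                    "pid": p.pid, "arm": arm, "week": w,
                    "mean_true_glucose": float(glucose.mean()),
                    "mean_cgm": m.mean_glucose, "sd_cgm": m.sd_glucose,
                    "tir": m.pct_3_9_to_10, "below_3_9": m.pct_below_3_9,
                    "above_10": m.pct_above_10,
                    "n_prandial": sum(1 for _ in log.of_kind(EventKind.meal_bolus)),
                    "n_correction": sum(1 for _ in log.of_kind(EventKind.correction_bolus)),
                    "n_basal_logs": sum(1 for _ in log.of_kind(EventKind.basal)),
                    "n_entries": len(log),
                }
            )
            if arm == "experimental":
                week_data = WeekData(cgm=cgm, events=log, week=w)
                rec, tstate = titrate_week(week_data, therapy, tstate, base_phys, settings)
                ledger.append((p.pid, w, rec))
                pending = rec

    return TrialResult(
        assignments=assignments,
        weekly=pd.DataFrame(weekly_rows),
        therapy_history=pd.DataFrame(therapy_rows),
        recommendations=ledger,
        cohort=cohort,
        weeks=weeks,
        seed=seed,
    )
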