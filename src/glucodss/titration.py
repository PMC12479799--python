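"""Weekly Bayesian titration engine.

Once a week the engine fits the glucoregulatory model to the previous
week's sensor and diary data (MAP estimate with log-normal priors and a
Laplace confidence), derives the therapy that would have been optimal for
that week, and blends it with the incumbent therapy in proportion to how
well the model explained the data and how confident the parameter
estimates are.  A safety rule prevents any insulin increase for meals (or
overnight basal) whose windows trended low, a weekly cap keeps changes
gradual, and recommendations that drift more than 30% from the last
approved prescription are flagged for clinician review.

The posterior of week t, inflated by a forgetting factor, becomes the
prior of week t+1, so information accumulates across the trial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .core import (
    MEALS,
    MealStrategy,
    TherapyParameters,
    parameter_changes,
    round_to_increment,
)
from .events import EventKind, EventLog
from .model import (
    MINUTES_PER_DAY,
    MMOL_PER_GRAM,
    CgmTrace,
    PatientPhysiology,
    steady_state_basal,
)
from . import kernels

#: Order of the fitted model parameters phi.
FIT_PARAMS = ("S_I", "G_b", "k_b", "f_breakfast", "f_lunch", "f_dinner")

OVERNIGHT_START_H, OVERNIGHT_END_H = 23.0, 7.0
POSTPRANDIAL_WINDOW_MIN = 240.0


class FitFailure(RuntimeError):
    """Model fit could not be performed; caller falls back to no change."""


@dataclass
class TitrationSettings:
    """Tunable knobs of the weekly engine (defaults are the study conditions)."""

    weekly_cap: float = 0.20  # max fractional move per parameter per week
    review_threshold: float = 0.30  # cumulative-change flag threshold
    sigma_cgm: float = 0.5  # residual sd assumed by the fit, mmol/L
    forgetting: float = 1.25  # posterior-sd inflation when rolling the prior
    auto_approve: bool = True  # clinician auto-approval for in-silico runs
    hypo_weight: float = 4.0  # cost-weight on glucose below the band
    band_low: float = 3.9
    band_high: float = 10.0
    nadir_threshold: float = 4.5  # "trending low" postprandial nadir
    hypo_threshold: float = 3.9
    fit_dt: float = 5.0  # replay integration step, minutes
    max_fun: int = 400  # optimizer budget per weekly fit
    #: nominal grams per meal type assumed for fixed-dose users (who log no
    #: carbs); the fitted bioavailability f_m absorbs the scale.
    nominal_grams: dict[str, float] = field(
        default_factory=lambda: {"breakfast": 45.0, "lunch": 60.0, "dinner": 70.0}
    )


@dataclass
class WeekData:
    """One week of observations consumed by the titrator."""

    cgm: CgmTrace
    events: EventLog
    week: int = 0


@dataclass
class PosteriorFit:
    """MAP fit of phi = (S_I, G_b, k_b, f_b, f_l, f_d) with Laplace sds."""

    log_map: np.ndarray  # log of MAP estimate, FIT_PARAMS order
    post_log_sd: np.ndarray
    prior_log_sd: np.ndarray
    r2: float
    n_obs: int

    @property
    def map_estimate(self) -> dict[str, float]:
        return dict(zip(FIT_PARAMS, np.exp(self.log_map)))

    def shrinkage(self) -> np.ndarray:
        """Per-parameter confidence s = clip(1 - (post sd / prior sd)^2, 0, 1)."""
        ratio = self.post_log_sd / self.prior_log_sd
        return np.clip(1.0 - ratio**2, 0.0, 1.0)

    def physiology(self, base: PatientPhysiology) -> PatientPhysiology:
        m = self.map_estimate
        return base.with_fitted(
            S_I=m["S_I"], G_b=m["G_b"], k_b=m["k_b"],
            f={"breakfast": m["f_breakfast"], "lunch": m["f_lunch"], "dinner": m["f_dinner"]},
        )


@dataclass
class TitrationState:
    """Iterated prior plus the reference therapy for the 30% review rule."""

    prior_log_median: np.ndarray
    prior_log_sd: np.ndarray
    initial_log_sd: np.ndarray
    reference: TherapyParameters
    week: int = 0

    @classmethod
    def initial(
        cls,
        therapy: TherapyParameters,
        base: PatientPhysiology,
        prior_sd: dict[str, float] | None = None,
    ) -> "TitrationState":
        sd = {"S_I": 0.4, "G_b": 0.20, "k_b": 0.35,
              "f_breakfast": 0.25, "f_lunch": 0.25, "f_dinner": 0.25}
        if prior_sd:
            sd.update(prior_sd)
        med = np.log(
            [base.S_I, base.G_b, base.k_b,
             base.f["breakfast"], base.f["lunch"], base.f["dinner"]]
        )
        sds = np.array([sd[p] for p in FIT_PARAMS])
        return cls(med, sds, sds.copy(), reference=therapy)


@dataclass
class Recommendation:
    """One weekly algorithm output."""

    therapy: TherapyParameters
    weights: dict[str, float]
    attenuations: list[str]
    flagged: bool
    approved: bool
    rationale: str
    changes: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# replay plumbing


def _week_events(
    week: WeekData, therapy: TherapyParameters, settings: TitrationSettings
):
    """Bolus and meal impulse lists from the diary.

    Meals are attached to meal-bolus entries; carb-counting users log grams,
    fixed-dose users get the nominal per-meal-type grams.
    """
    boluses: list[tuple[float, float]] = []
    meals: list[tuple[float, float, str]] = []
    for ev in week.events:
        if ev.kind is EventKind.basal:
            continue
        boluses.append((ev.timestamp, ev.delivered))
        if ev.kind is EventKind.meal_bolus:
            mt = ev.meal_type or "dinner"
            grams = ev.carbs
            if grams is None:
                grams = settings.nominal_grams.get(mt, 60.0)
            meals.append((ev.timestamp, grams, mt))
    return boluses, meals


class _Replayer:
    """Fast re-simulation of one week under candidate (phi, therapy)."""

    def __init__(
        self,
        week: WeekData,
        therapy: TherapyParameters,
        base: PatientPhysiology,
        settings: TitrationSettings,
    ):
        self.base = base
        self.settings = settings
        hist = week.cgm.historic()
        if len(hist) == 0:
            raise FitFailure("no historic CGM records")
        self.t0 = float(hist.times[0])
        dt = settings.fit_dt
        span = max(float(hist.times[-1] - self.t0), MINUTES_PER_DAY)
        self.n_steps = int(math.ceil(span / dt)) + 1
        self.dt = dt
        self.obs_idx = np.clip(
            np.round((hist.times - self.t0) / dt).astype(np.int64), 0, self.n_steps
        )
        self.obs_g = hist.glucose
        self.g0 = float(hist.glucose[0])

        boluses, meals = _week_events(week, therapy, settings)
        self.bolus_step = np.array(
            [int(round((t - self.t0) / dt)) for t, _ in boluses], dtype=np.int64
        )
        self.bolus_mU = np.array([u * 1000.0 for _, u in boluses])
        self.meal_step = np.array(
            [int(round((t - self.t0) / dt)) for t, _, _ in meals], dtype=np.int64
        )
        self.meal_grams = np.array([g for _, g, _ in meals])
        self.meal_type_idx = np.array(
            [MEALS.index(mt) if mt in MEALS else 2 for _, _, mt in meals], dtype=np.int64
        )
        ok_b = (self.bolus_step >= 0) & (self.bolus_step < self.n_steps)
        ok_m = (self.meal_step >= 0) & (self.meal_step < self.n_steps)
        self.bolus_step, self.bolus_mU = self.bolus_step[ok_b], self.bolus_mU[ok_b]
        self.meal_step = self.meal_step[ok_m]
        self.meal_grams = self.meal_grams[ok_m]
        self.meal_type_idx = self.meal_type_idx[ok_m]
        order = np.argsort(self.bolus_step, kind="stable")
        self.bolus_step, self.bolus_mU = self.bolus_step[order], self.bolus_mU[order]
        order = np.argsort(self.meal_step, kind="stable")
        self.meal_step = self.meal_step[order]
        self.meal_grams = self.meal_grams[order]
        self.meal_type_idx = self.meal_type_idx[order]

    def glucose(
        self,
        phi: np.ndarray,
        basal: float,
        bolus_mU: np.ndarray | None = None,
    ) -> np.ndarray:
        """Simulated glucose on the fit grid for phi (FIT_PARAMS order)."""
        p = self.base.as_array().copy()
        p[kernels.P_SI], p[kernels.P_GB], p[kernels.P_KB] = phi[0], phi[1], phi[2]
        f = phi[3:6]
        meal_mmol = self.meal_grams * MMOL_PER_GRAM * f[self.meal_type_idx]
        x0 = phi[0] * phi[2] * basal
        y0 = np.array([0.0, 0.0, 0.0, x0, 0.0, 0.0, self.g0])
        states = kernels.integrate(
            y0, self.n_steps, self.dt, p, basal,
            self.bolus_step, self.bolus_mU if bolus_mU is None else bolus_mU,
            self.meal_step, meal_mmol,
        )
        return states[:, 6]


# ---------------------------------------------------------------------------
# operations


def fit_patient_model(
    week: WeekData,
    state: TitrationState,
    therapy: TherapyParameters,
    base: PatientPhysiology,
    settings: TitrationSettings | None = None,
) -> PosteriorFit:
    """MAP fit of phi to one week of data, with Laplace posterior sds.

    Maximizes the Gaussian log-likelihood of the historic CGM residuals
    (sd ``settings.sigma_cgm``) plus the log-normal log-prior, by L-BFGS-B
    in log-parameter space starting from the prior median.  Requires at
    least two days of CGM and one logged bolus.
    """
    settings = settings or TitrationSettings()
    hist = week.cgm.historic()
    n_bolus = len(week.events.of_kind(EventKind.meal_bolus, EventKind.correction_bolus))
    if hist.span_days() < 2 or n_bolus < 1:
        raise FitFailure(
            f"insufficient data: {hist.span_days():.1f} CGM days, {n_bolus} boluses"
        )
    rep = _Replayer(week, therapy, base, settings)
    sigma2 = settings.sigma_cgm**2
    mu0, sd0 = state.prior_log_median, state.prior_log_sd

    def objective(logphi: np.ndarray) -> float:
        g = rep.glucose(np.exp(logphi), therapy.basal_dose)
        resid = rep.obs_g - g[rep.obs_idx]
        val = 0.5 * float(resid @ resid) / sigma2 + 0.5 * float(
            (((logphi - mu0) / sd0) ** 2).sum()
        )
        return val if math.isfinite(val) else 1e12

    bounds = [
        (mu0[0] - 2.0, mu0[0] + 2.0),   # S_I
        (mu0[1] - 0.7, mu0[1] + 0.7),   # G_b
        (mu0[2] - 1.5, mu0[2] + 1.5),   # k_b
    ] + [(math.log(0.3), 0.0)] * 3       # f in (0.3, 1]
    res = minimize(
        objective, mu0.copy(), method="L-BFGS-B", bounds=bounds,
        options={"maxfun": settings.max_fun, "ftol": 1e-12, "gtol": 1e-8},
    )
    if not np.all(np.isfinite(res.x)):
        raise FitFailure("optimizer returned non-finite parameters")
    log_map = res.x

    # goodness of fit on historic records
    g = rep.glucose(np.exp(log_map), therapy.basal_dose)
    resid = rep.obs_g - g[rep.obs_idx]
    ssr = float(resid @ resid)
    sst = float(((rep.obs_g - rep.obs_g.mean()) ** 2).sum())
    r2 = 1.0 - ssr / sst if sst > 0 else 0.0

    post_sd = _laplace_sd(objective, log_map, sd0)
    return PosteriorFit(
        log_map=log_map, post_log_sd=post_sd, prior_log_sd=sd0.copy(),
        r2=r2, n_obs=len(rep.obs_g),
    )


def _laplace_sd(objective, x: np.ndarray, prior_sd: np.ndarray, h: float = 1e-3) -> np.ndarray:
    """Posterior sds from the numerical Hessian of the negative log-posterior.

    Falls back to the prior sd (zero shrinkage) for directions in which the
    Hessian is not positive definite.
    """
    n = len(x)
    H = np.empty((n, n))
    f0 = objective(x)
    for i in range(n):
        ei = np.zeros(n); ei[i] = h
        H[i, i] = (objective(x + ei) - 2 * f0 + objective(x - ei)) / h**2
    for i in range(n):
        for j in range(i + 1, n):
            ei = np.zeros(n); ei[i] = h
            ej = np.zeros(n); ej[j] = h
            H[i, j] = H[j, i] = (
                objective(x + ei + ej) - objective(x + ei - ej)
                - objective(x - ei + ej) + objective(x - ei - ej)
            ) / (4 * h**2)
    try:
        cov = np.linalg.inv(H)
        var = np.diag(cov)
        if np.any(var <= 0) or not np.all(np.isfinite(var)):
            raise np.linalg.LinAlgError
        return np.minimum(np.sqrt(var), prior_sd * 10)
    except np.linalg.LinAlgError:
        return prior_sd.copy()


def _cost(glucose: np.ndarray, settings: TitrationSettings) -> float:
    lo = np.maximum(0.0, settings.band_low - glucose)
    hi = np.maximum(0.0, glucose - settings.band_high)
    return float(np.mean(settings.hypo_weight * lo**2 + hi**2))


def optimal_therapy(
    fit: PosteriorFit,
    therapy: TherapyParameters,
    week: WeekData,
    base: PatientPhysiology,
    settings: TitrationSettings | None = None,
) -> TherapyParameters:
    """Unconstrained optimum theta*: the therapy that would have been best
    last week under the fitted model.

    The basal dose is the closed-form fasting solution at the MAP estimate;
    each prandial parameter then minimizes the simulated weekly cost
    (quadratic penalties below 3.9 and above 10 mmol/L, hypoglycemia
    weighted 4x) replaying the week's meals, one bounded search per meal.
    """
    settings = settings or TitrationSettings()
    phys_hat = fit.physiology(base)
    phi = np.exp(fit.log_map)
    rep = _Replayer(week, therapy, base, settings)

    if therapy.glucose_target < phys_hat.G_b:
        basal_star = steady_state_basal(phys_hat, therapy.glucose_target)
    else:
        basal_star = therapy.basal_dose

    # per-meal insulin intensities (units/gram for CC, units for fixed dose)
    intens = {m: therapy.prandial_insulin_equivalent(m) for m in MEALS}
    carb_counting = therapy.meal_strategy is MealStrategy.carb_counting

    # replay uses the candidate prandial schedule instead of the logged
    # boluses: one bolus per meal, co-timed with the meal impulse
    rep.bolus_step = rep.meal_step.copy()

    def doses_mU(cur: dict[str, float]) -> np.ndarray:
        out = np.empty(len(rep.meal_step))
        for k in range(len(rep.meal_step)):
            m = MEALS[rep.meal_type_idx[k]]
            if carb_counting:
                out[k] = cur[m] * rep.meal_grams[k] * 1000.0
            else:
                out[k] = cur[m] * 1000.0
        return out

    def cost_for(cur: dict[str, float]) -> float:
        g = rep.glucose(phi, basal_star, bolus_mU=doses_mU(cur))
        return _cost(g, settings)

    # coordinate descent over the per-meal parameters, iterated to a joint
    # fixed point (a single pass is order-dependent)
    if len(rep.meal_step):
        for _sweep in range(4):
            max_move = 0.0
            for m in MEALS:
                if not np.any(rep.meal_type_idx == MEALS.index(m)):
                    continue
                base_val = intens[m]
                if base_val <= 0:
                    continue

                def obj(logu: float, meal=m, bv=base_val) -> float:
                    cur = dict(intens)
                    cur[meal] = bv * math.exp(logu)
                    # tiny anchor toward the incumbent: selects "no change"
                    # inside a zero-cost basin (glucose entirely in band)
                    drift = math.log(cur[meal] / therapy.prandial_insulin_equivalent(meal))
                    return cost_for(cur) + 1e-4 * drift * drift

                res = minimize_scalar(
                    obj, bounds=(math.log(0.3), math.log(3.0)), method="bounded",
                    options={"xatol": 5e-3},
                )
                intens[m] = base_val * math.exp(res.x)
                max_move = max(max_move, abs(res.x))
            if max_move < 0.02:
                break

    out = therapy.with_basal(max(basal_star, 1e-6))
    for m in MEALS:
        if intens[m] > 0:
            out = out.with_prandial(m, intens[m])
    return out


def blend(
    theta_star: TherapyParameters,
    theta_prev: TherapyParameters,
    fit: PosteriorFit,
) -> tuple[TherapyParameters, dict[str, float]]:
    """Confidence-weighted geometric mixture of optimum and incumbent.

    Per therapy parameter i the blend weight is w_i = max(0, R^2) * s_i,
    where s_i is the Laplace shrinkage of the model parameters that inform
    it (basal: S_I, G_b, k_b; meal m: S_I and f_m; the minimum is taken).
    Blending is in log scale, so w=1/2 gives the geometric mean.
    """
    s = dict(zip(FIT_PARAMS, fit.shrinkage()))
    quality = max(0.0, fit.r2)
    weights = {
        "basal": quality * min(s["S_I"], s["G_b"], s["k_b"]),
        "breakfast": quality * min(s["S_I"], s["f_breakfast"]),
        "lunch": quality * min(s["S_I"], s["f_lunch"]),
        "dinner": quality * min(s["S_I"], s["f_dinner"]),
    }
    star, prev = theta_star.titratable(), theta_prev.titratable()
    def _mix(w: float, a: float, b: float) -> float:
        """log-scale mixture, exact at the w = 0 / w = 1 limits."""
        if a <= 0 or b <= 0:
            return b
        if w <= 0:
            return b
        if w >= 1:
            return a
        return math.exp(w * math.log(a) + (1 - w) * math.log(b))

    out = theta_prev.with_basal(_mix(weights["basal"], star["basal"], prev["basal"]))
    for m in MEALS:
        if prev[m] <= 0 or star[m] <= 0:
            continue
        out = out.with_prandial(m, _mix(weights[m], star[m], prev[m]))
    return out, weights


def _overnight_mask(times: np.ndarray) -> np.ndarray:
    tod_h = (times % MINUTES_PER_DAY) / 60.0
    return (tod_h >= OVERNIGHT_START_H) | (tod_h < OVERNIGHT_END_H)


def hypo_windows(
    week: WeekData, settings: TitrationSettings | None = None
) -> tuple[set[str], bool]:
    """Meals with a low-trending postprandial window, and overnight hypo.

    A meal type is implicated when any 4-hour window after one of its
    logged boluses has a sensor nadir below 4.5 mmol/L (a reading below
    3.9 is a fortiori below that nadir).  Overnight (23:00-07:00) readings
    below 3.9 mmol/L implicate the basal dose.
    """
    settings = settings or TitrationSettings()
    t, g = week.cgm.times, week.cgm.glucose
    meals_low: set[str] = set()
    for ev in week.events.of_kind(EventKind.meal_bolus):
        mt = ev.meal_type
        if mt not in MEALS or mt in meals_low:
            continue
        m = (t >= ev.timestamp) & (t <= ev.timestamp + POSTPRANDIAL_WINDOW_MIN)
        if np.any(m) and float(g[m].min()) < settings.nadir_threshold:
            meals_low.add(mt)
    night = _overnight_mask(t)
    overnight_low = bool(np.any(g[night] < settings.hypo_threshold))
    return meals_low, overnight_low


def safety_attenuate(
    theta_blend: TherapyParameters,
    theta_prev: TherapyParameters,
    week: WeekData,
    settings: TitrationSettings | None = None,
) -> tuple[TherapyParameters, list[str]]:
    """One-sided safety rule: never more insulin where glucose trended low.

    For each meal type with a hypoglycemic postprandial window that week,
    the prandial parameter may not move toward more insulin than the
    incumbent (carb ratio not decreased, fixed dose not increased); with
    overnight hypoglycemia the basal dose may not increase.  Decreases
    always pass.
    """
    settings = settings or TitrationSettings()
    meals_low, overnight_low = hypo_windows(week, settings)
    attenuations: list[str] = []
    out = theta_blend
    prev = theta_prev.titratable()
    cur = theta_blend.titratable()
    for m in meals_low:
        if cur[m] > prev[m]:
            out = out.with_prandial(m, prev[m])
            attenuations.append(f"{m}: prandial insulin held (postprandial nadir < "
                                f"{settings.nadir_threshold} mmol/L)")
    if overnight_low and cur["basal"] > prev["basal"]:
        out = out.with_basal(prev["basal"])
        attenuations.append(
            f"basal: held (overnight glucose < {settings.hypo_threshold} mmol/L)"
        )
    return out, attenuations


def _round_ratio(cr: float) -> float:
    """Carb ratios are displayed to 0.1 g/U; ties round up (less insulin)."""
    return math.ceil(cr * 10 - 0.5 + 1e-9) / 10.0


def finalize(
    theta_safe: TherapyParameters,
    theta_prev: TherapyParameters,
    theta_reference: TherapyParameters,
    settings: TitrationSettings | None = None,
    approve: bool | None = None,
) -> Recommendation:
    """Cap, round and flag the recommendation.

    Every parameter is clipped to within +/-``weekly_cap`` of its
    predecessor on the insulin-equivalent scale, then rounded to the pen
    increment (carb ratios to 0.1 g/U), staying inside the cap window.  The
    recommendation is flagged when any parameter's cumulative change from
    the reference (baseline or last approved) exceeds the review threshold.
    """
    settings = settings or TitrationSettings()
    cap = settings.weekly_cap
    prev = theta_prev.titratable()
    safe = theta_safe.titratable()

    out = theta_prev
    capped = {}
    for name in safe:
        lo, hi = prev[name] * (1 - cap), prev[name] * (1 + cap)
        capped[name] = min(max(safe[name], lo), hi)

    def _round_within(value: float, inc: float, lo: float, hi: float, fallback: float) -> float:
        """Nearest multiple of ``inc`` that stays inside the cap window."""
        r = round_to_increment(value, inc)
        if r > hi + 1e-9:
            r = math.floor(hi / inc + 1e-9) * inc
        if r < lo - 1e-9:
            r = math.ceil(lo / inc - 1e-9) * inc
        if not (lo - 1e-9 <= r <= hi + 1e-9) or r <= 0:
            return fallback
        return r

    lo, hi = prev["basal"] * (1 - cap), prev["basal"] * (1 + cap)
    out = out.with_basal(
        _round_within(capped["basal"], theta_prev.basal_increment, lo, hi,
                      theta_prev.basal_dose)
    )

    for m in MEALS:
        if prev[m] <= 0:
            continue
        lo, hi = prev[m] * (1 - cap), prev[m] * (1 + cap)
        if theta_prev.meal_strategy is MealStrategy.carb_counting:
            # rounding happens on the displayed ratio (0.1 g/U); keep the
            # implied insulin intensity 1/CR inside the cap window
            cr = _round_ratio(1.0 / capped[m])
            cr_min = math.ceil(10.0 / hi - 1e-9) / 10.0
            cr_max = math.floor(10.0 / lo + 1e-9) / 10.0
            cr = min(max(cr, cr_min), cr_max)
            val = 1.0 / cr if cr_min <= cr_max and cr > 0 else prev[m]
            if not (lo - 1e-9 <= val <= hi + 1e-9):
                val = prev[m]
        else:
            val = _round_within(capped[m], theta_prev.bolus_increment, lo, hi, prev[m])
        out = out.with_prandial(m, val)

    changes = parameter_changes(out, theta_prev, theta_reference, settings.review_threshold)
    flagged = any(ch.flagged for ch in changes)
    approved = approve if approve is not None else (settings.auto_approve or not flagged)
    rationale = "; ".join(
        f"{ch.parameter}: {ch.previous:.3g} -> {ch.new:.3g} "
        f"(cumulative {ch.cumulative_from_reference:+.0%})"
        for ch in changes
    )
    return Recommendation(
        therapy=out, weights={}, attenuations=[], flagged=flagged,
        approved=approved, rationale=rationale, changes=changes,
    )


def titrate_week(
    week: WeekData,
    therapy: TherapyParameters,
    state: TitrationState,
    base: PatientPhysiology,
    settings: TitrationSettings | None = None,
) -> tuple[Recommendation, TitrationState]:
    """Full weekly pipeline: fit -> optimal -> blend -> safety -> finalize.

    On fit failure (or insufficient data) the recommendation is "no
    change".  The returned state carries the rolled-forward prior and the
    updated reference therapy for the review rule.
    """
    settings = settings or TitrationSettings()
    try:
        fit = fit_patient_model(week, state, therapy, base, settings)
    except FitFailure as exc:
        rec = Recommendation(
            therapy=therapy, weights={}, attenuations=[], flagged=False,
            approved=True, rationale=f"no change: {exc}",
        )
        new_state = TitrationState(
            state.prior_log_median.copy(), state.prior_log_sd.copy(),
            state.initial_log_sd.copy(), state.reference, state.week + 1,
        )
        return rec, new_state

    theta_star = optimal_therapy(fit, therapy, week, base, settings)
    theta_blend, weights = blend(theta_star, therapy, fit)
    theta_safe, attenuations = safety_attenuate(theta_blend, therapy, week, settings)
    rec = finalize(theta_safe, therapy, state.reference, settings)
    rec.weights = weights
    rec.attenuations = attenuations
    if attenuations:
        rec.rationale += " | safety: " + "; ".join(attenuations)

    new_sd = np.minimum(fit.post_log_sd * settings.forgetting, state.initial_log_sd)
    reference = state.reference
    if rec.flagged and rec.approved:
        reference = rec.therapy
    new_state = TitrationState(
        prior_log_median=fit.log_map.copy(),
        prior_log_sd=new_sd,
        initial_log_sd=state.initial_log_sd.copy(),
        reference=reference,
        week=state.week + 1,
    )
    return rec, new_state
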