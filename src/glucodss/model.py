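"""Glucoregulatory model: virtual patient, forward simulation, CGM observation.

The model is a Bergman-style minimal model (glucose effectiveness S_G,
remote insulin action X with sensitivity S_I) extended with a two-compartment
gut absorption chain and a two-compartment subcutaneous depot for
rapid-acting insulin.  The once-daily long-acting basal dose is approximated
as a constant plasma-insulin contribution k_b * B (appropriate for degludec
or glargine at steady state).

The same model serves as the in-silico virtual patient (with intermittently
scanned CGM observation on top) and as the fitting model inside the weekly
titration engine; the titration logic is agnostic to the model's internals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import kernels
from .core import InvalidArgument
from .events import TrendArrow

#: mmol of glucose per gram of carbohydrate (molar mass 180.16 g/mol).
MMOL_PER_GRAM = 1000.0 / 180.16

#: Freestyle-style sensor reporting range, mmol/L.
SENSOR_MIN, SENSOR_MAX = 2.2, 27.8

HISTORIC_INTERVAL_MIN = 15

MINUTES_PER_DAY = 1440


class IntegrationFailure(RuntimeError):
    """Non-finite state encountered during simulation."""


@dataclass
class PatientPhysiology:
    """Virtual-patient parameters of the glucoregulatory model.

    Rates are per minute; ``f`` holds the per-meal-type carbohydrate
    bioavailability fractions in (0, 1].
    """

    S_I: float = 6.0e-4  # insulin sensitivity, 1/min per (mU/L)
    S_G: float = 0.012  # glucose effectiveness, 1/min
    G_b: float = 15.5  # insulin-free equilibrium glucose, mmol/L
    p2: float = 0.02  # remote-insulin activation rate, 1/min
    tau_I: float = 55.0  # subcutaneous rapid-insulin time constant, min
    k_e: float = 0.12  # plasma insulin elimination, 1/min
    V_I: float = 12.0  # insulin distribution volume, L
    k_b: float = 0.9  # plasma insulin per basal unit/day, (mU/L)/(U/day)
    tau_m: float = 40.0  # meal absorption time constant, min
    V_G: float = 13.0  # glucose distribution volume, L
    f: dict[str, float] = field(
        default_factory=lambda: {"breakfast": 0.85, "lunch": 0.85, "dinner": 0.85}
    )

    def __post_init__(self) -> None:
        for name in ("S_I", "S_G", "G_b", "p2", "tau_I", "k_e", "V_I", "k_b", "tau_m", "V_G"):
            if getattr(self, name) <= 0:
                raise InvalidArgument(f"{name} must be > 0")
        for m, v in self.f.items():
            if not 0 < v <= 1:
                raise InvalidArgument(f"f[{m}] must be in (0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.S_I, self.S_G, self.G_b, self.p2, self.tau_I,
             self.k_e, self.V_I, self.k_b, self.tau_m, self.V_G]
        )

    def bioavailability(self, meal_type: str | None) -> float:
        if meal_type in self.f:
            return self.f[meal_type]
        return self.f.get("dinner", 0.85)  # bedtime snacks absorb like dinner

    def fasting_glucose(self, basal: float) -> float:
        """Fasting equilibrium glucose under a basal dose B (units/day)."""
        return self.S_G * self.G_b / (self.S_G + self.S_I * self.k_b * basal)

    def isf_estimate(self) -> float:
        """Model-implied insulin sensitivity factor (mmol/L per unit).

        Approximates the total glucose lowering of a 1-unit bolus near the
        target range: integrated remote action S_I * 1000/(k_e V_I) applied
        to a nominal 6 mmol/L operating glucose.
        """
        return self.S_I * 1000.0 / (self.k_e * self.V_I) * 6.0

    def with_fitted(self, S_I: float, G_b: float, k_b: float, f: dict[str, float]):
        return replace(self, S_I=S_I, G_b=G_b, k_b=k_b, f=dict(f))


def steady_state_basal(physiology: PatientPhysiology, target: float) -> float:
    """Closed-form basal dose (units/day) whose fasting equilibrium is ``target``.

    B = S_G (G_b - target) / (S_I k_b target); requires 0 < target < G_b.
    """
    if not 0 < target:
        raise InvalidArgument("target must be > 0")
    if target >= physiology.G_b:
        raise InvalidArgument(
            f"no solution: target {target} >= insulin-free equilibrium {physiology.G_b}"
        )
    return (
        physiology.S_G
        * (physiology.G_b - target)
        / (physiology.S_I * physiology.k_b * target)
    )


def initial_fasting_state(physiology: PatientPhysiology, basal: float) -> np.ndarray:
    """Steady fasting state (no meals, no boluses) under a basal dose."""
    g = physiology.fasting_glucose(basal)
    x = physiology.S_I * physiology.k_b * basal
    return np.array([0.0, 0.0, 0.0, x, 0.0, 0.0, g])


@dataclass
class SimResult:
    """Minute-grid simulation output."""

    times: np.ndarray  # minutes
    states: np.ndarray  # (n, 7)

    @property
    def glucose(self) -> np.ndarray:
        return self.states[:, 6]

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1].copy()


def simulate(
    physiology: PatientPhysiology,
    basal: float,
    boluses: list[tuple[float, float]],
    meals: list[tuple[float, float, str]],
    horizon_days: float,
    initial_state: np.ndarray | None = None,
    dt: float = 1.0,
    t0: float = 0.0,
) -> SimResult:
    """Simulate glucose over ``horizon_days``.

    ``boluses`` are (time min, units); ``meals`` are (time min, grams,
    meal type).  Times are absolute and must fall within
    ``[t0, t0 + horizon)``.  Returns states on the ``dt``-minute grid.
    """
    horizon = horizon_days * MINUTES_PER_DAY
    n_steps = int(round(horizon / dt))
    if initial_state is None:
        initial_state = initial_fasting_state(physiology, basal)
    y0 = np.asarray(initial_state, dtype=float)

    def _steps(times: list[float]) -> np.ndarray:
        idx = np.array([int(round((t - t0) / dt)) for t in times], dtype=np.int64)
        if len(idx) and (idx.min() < 0 or idx.max() >= n_steps):
            raise InvalidArgument("event outside the simulation horizon")
        return idx

    b_sorted = sorted(boluses)
    m_sorted = sorted(meals)
    bolus_step = _steps([t for t, _ in b_sorted])
    bolus_mU = np.array([u * 1000.0 for _, u in b_sorted], dtype=float)
    meal_step = _steps([t for t, _, _ in m_sorted])
    meal_mmol = np.array(
        [g * MMOL_PER_GRAM * physiology.bioavailability(mt) for _, g, mt in m_sorted],
        dtype=float,
    )
    states = kernels.integrate(
        y0, n_steps, dt, physiology.as_array(), basal,
        bolus_step, bolus_mU, meal_step, meal_mmol,
    )
    if not np.all(np.isfinite(states)):
        raise IntegrationFailure(
            f"non-finite state at step {int(np.argmin(np.isfinite(states[:, 6])))}"
        )
    times = t0 + dt * np.arange(n_steps + 1)
    return SimResult(times=times, states=states)


# ---------------------------------------------------------------------------
# CGM observation


@dataclass
class CgmTrace:
    """Observed sensor series: 15-min historic records plus user scans."""

    times: np.ndarray  # minutes since epoch
    glucose: np.ndarray  # mmol/L
    record_type: np.ndarray  # 0 = historic, 1 = scan

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.glucose = np.asarray(self.glucose, dtype=float)
        self.record_type = np.asarray(self.record_type, dtype=int)
        order = np.argsort(self.times, kind="stable")
        self.times = self.times[order]
        self.glucose = self.glucose[order]
        self.record_type = self.record_type[order]

    def __len__(self) -> int:
        return len(self.times)

    def historic(self) -> "CgmTrace":
        m = self.record_type == 0
        return CgmTrace(self.times[m], self.glucose[m], self.record_type[m])

    def span_days(self) -> float:
        if len(self.times) < 2:
            return 0.0
        return (self.times[-1] - self.times[0]) / MINUTES_PER_DAY


@dataclass
class SensorModel:
    """Intermittently scanned CGM error model.

    AR(1)-correlated Gaussian noise (``ar_coeff`` is the correlation at a
    15-minute lag) with an optional negative bias below ``low_threshold``
    emulating the sensor's tendency to over-read hypoglycemia exposure.
    """

    noise_sd: float = 0.4  # mmol/L, marginal
    ar_coeff: float = 0.5  # correlation at 15-min lag
    low_bias: float = 0.0  # mmol/L subtracted below the threshold
    low_threshold: float = 5.0

    def noise_path(self, n_minutes: int, rng: np.random.Generator) -> np.ndarray:
        """Stationary AR(1) noise sampled on the minute grid."""
        if self.noise_sd == 0:
            return np.zeros(n_minutes)
        from scipy.signal import lfilter

        rho = self.ar_coeff ** (1.0 / HISTORIC_INTERVAL_MIN) if self.ar_coeff > 0 else 0.0
        z = rng.standard_normal(n_minutes)
        z[0] /= math.sqrt(1.0 - rho * rho)  # stationary start
        scale = self.noise_sd * math.sqrt(1.0 - rho * rho)
        return lfilter([scale], [1.0, -rho], z)

    def report(self, truth: np.ndarray, noise: np.ndarray) -> np.ndarray:
        obs = truth + noise
        if self.low_bias:
            obs = np.where(truth < self.low_threshold, obs - self.low_bias, obs)
        return np.clip(obs, SENSOR_MIN, SENSOR_MAX)


def observe_cgm(
    times: np.ndarray,
    glucose: np.ndarray,
    sensor: SensorModel,
    scan_times: list[float] | np.ndarray = (),
    seed: int | np.random.Generator = 0,
    noise: np.ndarray | None = None,
) -> CgmTrace:
    """Sample a CGM record from a minute-grid truth trace.

    Historic records are taken every 15 minutes from the first time point;
    scans at the requested times (rounded to the grid).  A shared noise path
    may be passed in so dosing decisions and the stored record see the same
    sensor error; otherwise one is drawn from ``seed``.
    """
    times = np.asarray(times, dtype=float)
    glucose = np.asarray(glucose, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if noise is None:
        noise = sensor.noise_path(len(times), rng)
    obs = sensor.report(glucose, noise)

    hist_idx = np.arange(0, len(times), HISTORIC_INTERVAL_MIN)
    t0 = times[0]
    dt = times[1] - times[0] if len(times) > 1 else 1.0
    scan_idx = np.array(
        sorted({int(round((t - t0) / dt)) for t in scan_times}), dtype=int
    )
    if len(scan_idx) and (scan_idx.min() < 0 or scan_idx.max() >= len(times)):
        raise InvalidArgument("scan time outside the trace")

    all_t = np.concatenate([times[hist_idx], times[scan_idx]])
    all_g = np.concatenate([obs[hist_idx], obs[scan_idx]])
    all_r = np.concatenate([np.zeros(len(hist_idx), int), np.ones(len(scan_idx), int)])
    return CgmTrace(all_t, all_g, all_r)


def arrow_from_slope(delta_15min: float) -> TrendArrow:
    """Trend arrow from the glucose change over the trailing 15 minutes."""
    if delta_15min >= 1.7:
        return TrendArrow.rising_fast
    if delta_15min >= 0.8:
        return TrendArrow.rising
    if delta_15min <= -1.7:
        return TrendArrow.falling_fast
    if delta_15min <= -0.8:
        return TrendArrow.falling
    return TrendArrow.stable
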