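"""Virtual-participant sampling: physiology, mis-specified therapy, behaviour.

Each participant has a "true" physiology drawn from a log-normal
population, an initial prescription derived from the model-implied oracle
therapy but perturbed by multiplicative log-normal error (systematically
under-dosed — this is the suboptimally controlled population the trial
enrolled), and an adherence profile governing how often meals are bolused
through the app, basal doses logged, and corrections taken.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import AdherenceConfig, MealsConfig, PopulationConfig
from .core import MEALS, MealStrategy, TherapyParameters, round_to_increment
from .model import MMOL_PER_GRAM, PatientPhysiology, steady_state_basal


@dataclass
class AdherenceProfile:
    """Per-participant behaviour rates."""

    p_meal_bolus: float  # probability a meal is bolused via the app
    p_basal_log: float  # probability the daily basal dose is logged
    correction_rate: float  # correction-bolus attempts per day
    p_override: float  # probability a computed dose is overridden


@dataclass
class VirtualParticipant:
    pid: int
    physiology: PatientPhysiology
    therapy: TherapyParameters  # initial (mis-specified) prescription
    stratum: str  # "regular" or "new" sensor user
    adherence: AdherenceProfile
    baseline_hba1c: float = float("nan")  # estimated (GMI), set after burn-in


def oracle_prandial_intensity(phys: PatientPhysiology, meal: str) -> float:
    """Approximate insulin-to-carb need, units per gram.

    Balances the total glucose appearance of one gram (f * 5.551 mmol /
    V_G) against the integrated action of one unit of rapid insulin
    (S_I * 1000 / (k_e V_I)) applied at an operating glucose of ~7 mmol/L.
    The weekly titrator refines this; it only anchors the initial scale.
    """
    per_unit = phys.S_I * 1000.0 / (phys.k_e * phys.V_I) * 7.0
    per_gram = phys.bioavailability(meal) * MMOL_PER_GRAM / phys.V_G
    return per_gram / per_unit


def sample_physiology(rng: np.random.Generator, pop: PopulationConfig) -> PatientPhysiology:
    f = {m: float(rng.uniform(pop.f_low, pop.f_high)) for m in MEALS}
    return PatientPhysiology(
        S_I=pop.si_median * math.exp(rng.normal(0, pop.si_log_sd)),
        S_G=pop.s_g,
        G_b=pop.gb_median * math.exp(rng.normal(0, pop.gb_log_sd)),
        p2=pop.p2,
        tau_I=pop.tau_i,
        k_e=pop.k_e,
        V_I=pop.v_i,
        k_b=pop.kb_median * math.exp(rng.normal(0, pop.kb_log_sd)),
        tau_m=pop.tau_m,
        V_G=pop.v_g,
        f=f,
    )


def sample_participant(
    pid: int,
    rng: np.random.Generator,
    pop: PopulationConfig,
    adherence: AdherenceConfig,
    meals: MealsConfig,
) -> VirtualParticipant:
    """Draw one participant (baseline HbA1c filled in later by burn-in)."""
    phys = sample_physiology(rng, pop)
    # a patient whose insulin-free equilibrium is near the glucose target
    # cannot be hyperglycemic and would fail screening; redraw
    while phys.G_b <= pop.glucose_target + 2.0:
        phys = sample_physiology(rng, pop)
    stratum = "regular" if rng.random() < pop.regular_user_fraction else "new"
    carb_counting = rng.random() < pop.carb_counting_fraction
    basal_inc = float(rng.choice([2.0, 1.0, 0.5], p=[0.048, 0.905, 0.047]))
    bolus_inc = float(rng.choice([1.0, 0.5], p=[0.78, 0.22]))

    # one shared under-dosing bias per participant (how far their whole
    # regimen sits from their oracle), plus per-parameter mis-specification
    bias = rng.normal(pop.therapy_bias, pop.therapy_bias_sd)
    err = lambda: math.exp(bias + rng.normal(0, pop.therapy_error_sd))  # noqa: E731
    oracle_basal = steady_state_basal(phys, pop.glucose_target)
    basal = max(basal_inc, round_to_increment(oracle_basal * err(), basal_inc))

    isf = max(0.5, round(phys.isf_estimate() * 10) / 10)
    if carb_counting:
        cr = {}
        for m in MEALS:
            intensity = oracle_prandial_intensity(phys, m) * err()
            cr[m] = float(np.clip(round(1.0 / intensity, 1), 3.0, 30.0))
        therapy = TherapyParameters(
            basal_dose=basal, meal_strategy=MealStrategy.carb_counting,
            carb_ratio=cr, isf=isf, glucose_target=pop.glucose_target,
            active_insulin_time=pop.active_insulin_time,
            basal_increment=basal_inc, bolus_increment=bolus_inc,
        )
    else:
        fd = {}
        for m in MEALS:
            intensity = oracle_prandial_intensity(phys, m) * err()
            dose = intensity * meals.grams_median[m]
            fd[m] = max(bolus_inc, round_to_increment(dose, bolus_inc))
        therapy = TherapyParameters(
            basal_dose=basal, meal_strategy=MealStrategy.fixed_dose,
            fixed_dose=fd, isf=isf, glucose_target=pop.glucose_target,
            active_insulin_time=pop.active_insulin_time,
            basal_increment=basal_inc, bolus_increment=bolus_inc,
        )

    profile = AdherenceProfile(
        p_meal_bolus=float(rng.beta(adherence.meal_bolus_beta_a, adherence.meal_bolus_beta_b)),
        p_basal_log=float(rng.beta(adherence.basal_log_beta_a, adherence.basal_log_beta_b)),
        correction_rate=float(
            adherence.correction_rate_median
            * math.exp(rng.normal(0, adherence.correction_rate_log_sd))
        ),
        p_override=adherence.override_probability,
    )
    return VirtualParticipant(
        pid=pid, physiology=phys, therapy=therapy, stratum=stratum, adherence=profile
    )


def permuted_block_randomize(
    participants: list[VirtualParticipant],
    seed: int | np.random.Generator,
    block_sizes: dict[str, int] | None = None,
    force_balance: bool = False,
) -> dict[int, str]:
    """Stratified permuted-block 1:1 randomization.

    Within each sensor-use stratum, assignments come in randomly permuted
    balanced blocks — size 10 for regular users and 4 for new users — so
    arm totals never drift by more than half a block within a stratum.

    With ``force_balance`` the sequence is redrawn until the overall
    allocation is exactly 1:1 (to within one for an odd cohort), emulating
    a coordinator preparing the envelope sequence for the target per-arm
    enrollment; incomplete trailing blocks otherwise allow small overall
    imbalance.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    block_sizes = block_sizes or {"regular": 10, "new": 4}

    def draw() -> dict[int, str]:
        out: dict[int, str] = {}
        for stratum in ("regular", "new"):
            members = [p.pid for p in participants if p.stratum == stratum]
            b = block_sizes[stratum]
            assigned: list[str] = []
            while len(assigned) < len(members):
                block = ["experimental"] * (b // 2) + ["control"] * (b // 2)
                rng.shuffle(block)
                assigned.extend(block)
            for pid, arm in zip(members, assigned):
                out[pid] = arm
        return out

    target = len(participants) % 2
    best = draw()
    if force_balance:
        for _ in range(500):
            n_exp = sum(a == "experimental" for a in best.values())
            if abs(2 * n_exp - len(participants)) <= target:
                break
            best = draw()
    return best
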