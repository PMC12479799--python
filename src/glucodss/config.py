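"""Run configuration: population, sensor, titration, adherence and trial blocks.

Configs are strict (unknown keys rejected) and safety-relevant titration
keys carry no silent overrides: what you see in the file is what runs.
YAML is the on-disk form.
"""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict, Field

from .model import PatientPhysiology, SensorModel
from .titration import TitrationSettings


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PopulationConfig(_Strict):
    """Log-normal virtual-patient population and initial-therapy error.

    Medians define the fitting prior; the log-sds the inter-patient
    variability.  Kinetics (p2, tau_I, k_e, V_I, tau_m, V_G, S_G) are fixed
    at population values for identifiability from sparse scanned-CGM data.
    ``therapy_bias`` / ``therapy_error_sd`` parameterize the multiplicative
    log-normal mis-specification of each initial insulin parameter relative
    to the patient's model-implied oracle therapy; the bias is the single
    calibration dial that places the cohort at its baseline HbA1c
    distribution.
    """

    si_median: float = 6.0e-4
    si_log_sd: float = 0.35
    gb_median: float = 15.6
    gb_log_sd: float = 0.42
    kb_median: float = 0.9
    kb_log_sd: float = 0.20
    f_low: float = 0.75
    f_high: float = 0.95
    s_g: float = 0.012
    p2: float = 0.02
    tau_i: float = 55.0
    k_e: float = 0.12
    v_i: float = 12.0
    tau_m: float = 40.0
    v_g: float = 13.0
    therapy_bias: float = -0.85  # log-scale under-dosing of initial therapy
    therapy_bias_sd: float = 0.90  # participant-level spread of that bias
    therapy_error_sd: float = 0.25  # per-parameter mis-specification
    carb_counting_fraction: float = 0.60
    regular_user_fraction: float = 0.76
    glucose_target: float = 6.0
    active_insulin_time: float = 4.0
    min_baseline_hba1c: float = 7.5  # inclusion criterion, estimated

    def base_physiology(self) -> PatientPhysiology:
        """Population-median physiology: the fitting model's fixed kinetics
        and the initial prior medians."""
        return PatientPhysiology(
            S_I=self.si_median, S_G=self.s_g, G_b=self.gb_median, p2=self.p2,
            tau_I=self.tau_i, k_e=self.k_e, V_I=self.v_i, k_b=self.kb_median,
            tau_m=self.tau_m, V_G=self.v_g,
            f={m: (self.f_low + self.f_high) / 2 for m in ("breakfast", "lunch", "dinner")},
        )


class SensorConfig(_Strict):
    noise_sd: float = 0.4
    ar_coeff: float = 0.5
    low_bias: float = 0.0
    low_threshold: float = 5.0

    def sensor_model(self) -> SensorModel:
        return SensorModel(self.noise_sd, self.ar_coeff, self.low_bias, self.low_threshold)


class TitrationConfig(_Strict):
    weekly_cap: float = 0.20
    review_threshold: float = 0.30
    sigma_cgm: float = 0.5
    forgetting: float = 1.25
    auto_approve: bool = True
    hypo_weight: float = 4.0
    band_low: float = 3.9
    band_high: float = 10.0

    def settings(self) -> TitrationSettings:
        return TitrationSettings(
            weekly_cap=self.weekly_cap, review_threshold=self.review_threshold,
            sigma_cgm=self.sigma_cgm, forgetting=self.forgetting,
            auto_approve=self.auto_approve, hypo_weight=self.hypo_weight,
            band_low=self.band_low, band_high=self.band_high,
        )


class AdherenceConfig(_Strict):
    """Behavioural calibration.

    Beta parameters put the cohort medians at about 0.90 per-meal bolus
    probability (3 meals/day -> 2.7 prandial uses/day) and 0.92 daily basal
    logging; correction attempts follow a per-participant log-normal daily
    rate with median 0.56.
    """

    meal_bolus_beta_a: float = 15.33
    meal_bolus_beta_b: float = 2.0
    basal_log_beta_a: float = 13.75
    basal_log_beta_b: float = 1.5
    correction_rate_median: float = 0.56
    correction_rate_log_sd: float = 0.9
    override_probability: float = 0.08
    override_scale_low: float = 0.7
    override_scale_high: float = 1.3


class MealsConfig(_Strict):
    """Three daily meals at jittered clock times with log-normal sizes."""

    times_h: dict[str, float] = Field(
        default_factory=lambda: {"breakfast": 7.5, "lunch": 12.5, "dinner": 18.5}
    )
    time_jitter_min: float = 40.0
    grams_median: dict[str, float] = Field(
        default_factory=lambda: {"breakfast": 45.0, "lunch": 60.0, "dinner": 70.0}
    )
    grams_log_sd: float = 0.25


class TrialConfig(_Strict):
    n_participants: int = 84
    weeks: int = 12
    seed: int = 20
    control_edits: bool = False  # sparse standard-care edits in control arm


class RunConfig(_Strict):
    population: PopulationConfig = Field(default_factory=PopulationConfig)
    sensor: SensorConfig = Field(default_factory=SensorConfig)
    titration: TitrationConfig = Field(default_factory=TitrationConfig)
    adherence: AdherenceConfig = Field(default_factory=AdherenceConfig)
    meals: MealsConfig = Field(default_factory=MealsConfig)
    trial: TrialConfig = Field(default_factory=TrialConfig)


def default_config() -> RunConfig:
    return RunConfig()


def load_config(path) -> RunConfig:
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(data)


def save_config(config: RunConfig, path) -> None:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=False)
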