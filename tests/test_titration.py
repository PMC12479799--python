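"""Weekly titration engine: fitting, blending, safety, capping, iteration."""

import numpy as np
import pytest

import glucodss as g
from glucodss.config import default_config
from glucodss.events import DoseEvent, EventKind, EventLog
from glucodss.model import CgmTrace
from glucodss.titration import (
    FIT_PARAMS,
    PosteriorFit,
    TitrationSettings,
    TitrationState,
    WeekData,
    blend,
    finalize,
    fit_patient_model,
    optimal_therapy,
    safety_attenuate,
    titrate_week,
)

from conftest import build_logged_week


@pytest.fixture(scope="module")
def base():
    return default_config().population.base_physiology()


def _fit_with(log_map, post_sd, prior_sd, r2):
    return PosteriorFit(
        log_map=np.asarray(log_map, float),
        post_log_sd=np.asarray(post_sd, float),
        prior_log_sd=np.asarray(prior_sd, float),
        r2=r2, n_obs=672,
    )


class TestBlend:
    def _therapies(self):
        prev = g.TherapyParameters(
            basal_dose=10.0, meal_strategy="fixed_dose",
            fixed_dose={"breakfast": 10.0, "lunch": 10.0, "dinner": 10.0},
        )
        star = g.TherapyParameters(
            basal_dose=40.0, meal_strategy="fixed_dose",
            fixed_dose={"breakfast": 40.0, "lunch": 40.0, "dinner": 40.0},
        )
        return prev, star

    def test_zero_weight_returns_previous(self, base):
        prev, star = self._therapies()
        fit = _fit_with(np.zeros(6), np.ones(6), np.ones(6), r2=0.0)  # shrinkage 0
        out, w = blend(star, prev, fit)
        assert all(v == 0.0 for v in w.values())
        assert out.titratable() == prev.titratable()

    def test_unit_weight_returns_optimum(self, base):
        prev, star = self._therapies()
        fit = _fit_with(np.zeros(6), np.zeros(6), np.ones(6), r2=1.0)  # shrinkage 1
        out, w = blend(star, prev, fit)
        assert all(v == pytest.approx(1.0) for v in w.values())
        assert out.titratable() == pytest.approx(star.titratable())

    def test_half_weight_is_geometric_mean(self, base):
        prev, star = self._therapies()
        sd = np.full(6, np.sqrt(0.5))  # shrinkage = 1 - 0.5 = 0.5
        fit = _fit_with(np.zeros(6), sd, np.ones(6), r2=1.0)
        out, w = blend(star, prev, fit)
        assert all(v == pytest.approx(0.5) for v in w.values())
        assert out.basal_dose == pytest.approx(20.0)  # geometric mean of 10, 40
        assert out.fixed_dose["lunch"] == pytest.approx(20.0)

    def test_negative_r2_clamps_to_zero(self, base):
        prev, star = self._therapies()
        fit = _fit_with(np.zeros(6), np.zeros(6), np.ones(6), r2=-3.0)
        out, w = blend(star, prev, fit)
        assert out.titratable() == prev.titratable()


def _flat_week(glucose_values, times, meal_events=()):
    cgm = CgmTrace(np.asarray(times, float), np.asarray(glucose_values, float),
                   np.zeros(len(times), int))
    log = EventLog()
    for t, mt in meal_events:
        log.append(DoseEvent(timestamp=float(t), kind=EventKind.meal_bolus,
                             delivered=5.0, carbs=60.0, meal_type=mt))
    return WeekData(cgm=cgm, events=log, week=0)


class TestSafetyRule:
    def _therapy(self, basal=20.0, doses=(8.0, 8.0, 8.0)):
        return g.TherapyParameters(
            basal_dose=basal, meal_strategy="fixed_dose",
            fixed_dose=dict(zip(("breakfast", "lunch", "dinner"), doses)),
        )

    def test_inert_without_hypoglycemia(self):
        times = np.arange(0, 7 * 1440, 15.0)
        week = _flat_week(np.full(len(times), 7.0), times,
                         [(d * 1440 + 480, "breakfast") for d in range(7)])
        prev = self._therapy()
        want = self._therapy(doses=(10.0, 10.0, 10.0))
        out, att = safety_attenuate(want, prev, week)
        assert att == []
        assert out.fixed_dose["breakfast"] == 10.0

    def test_postprandial_nadir_blocks_increase(self):
        times = np.arange(0, 7 * 1440, 15.0)
        glucose = np.full(len(times), 7.0)
        glucose[np.argmin(np.abs(times - 600))] = 3.5  # 10:00 day 0, in b'fast window
        week = _flat_week(glucose, times, [(480, "breakfast")])
        prev = self._therapy()
        want = self._therapy(doses=(10.0, 10.0, 10.0))
        out, att = safety_attenuate(want, prev, week)
        assert out.fixed_dose["breakfast"] == 8.0  # capped at previous
        assert out.fixed_dose["lunch"] == 10.0  # other meals unaffected
        assert any("breakfast" in a for a in att)

    def test_nadir_4_4_counts_as_trending_low(self):
        times = np.arange(0, 1440, 15.0)
        glucose = np.full(len(times), 7.0)
        glucose[np.argmin(np.abs(times - 700))] = 4.4
        week = _flat_week(glucose, times, [(480, "breakfast")])
        out, att = safety_attenuate(
            self._therapy(doses=(10, 8, 8)), self._therapy(), week
        )
        assert out.fixed_dose["breakfast"] == 8.0

    def test_overnight_hypo_one_sided_on_basal(self):
        times = np.arange(0, 7 * 1440, 15.0)
        glucose = np.full(len(times), 7.0)
        glucose[np.argmin(np.abs(times - (2 * 1440 + 180)))] = 3.7  # 03:00
        week = _flat_week(glucose, times)
        # requested increase 20 -> 22 is held
        out, att = safety_attenuate(self._therapy(basal=22.0), self._therapy(20.0), week)
        assert out.basal_dose == 20.0
        assert any("basal" in a for a in att)
        # requested decrease 20 -> 18 passes
        out2, _ = safety_attenuate(self._therapy(basal=18.0), self._therapy(20.0), week)
        assert out2.basal_dose == 18.0

    def test_carb_ratio_direction(self):
        times = np.arange(0, 1440, 15.0)
        glucose = np.full(len(times), 7.0)
        glucose[np.argmin(np.abs(times - 560))] = 3.0
        week = _flat_week(glucose, times, [(480, "breakfast")])
        prev = g.TherapyParameters(
            basal_dose=20, meal_strategy="carb_counting",
            carb_ratio={"breakfast": 10.0, "lunch": 10.0, "dinner": 10.0},
        )
        want = prev.with_prandial("breakfast", 1 / 8.0)  # CR 10 -> 8: more insulin
        out, att = safety_attenuate(want, prev, week)
        assert out.carb_ratio["breakfast"] == pytest.approx(10.0)


class TestFinalize:
    def _prev(self):
        return g.TherapyParameters(
            basal_dose=20.0, meal_strategy="fixed_dose",
            fixed_dose={"breakfast": 8.0, "lunch": 8.0, "dinner": 8.0},
            basal_increment=1.0, bolus_increment=0.5,
        )

    def test_weekly_cap(self):
        prev = self._prev()
        want = prev.with_basal(30.0)
        rec = finalize(want, prev, prev)
        assert rec.therapy.basal_dose == 24.0  # 20 * 1.2

    def test_flag_via_cumulative_change(self):
        prev = self._prev()
        reference = prev.with_basal(18.0)
        want = prev.with_basal(24.0)
        rec = finalize(want, prev, reference)
        assert rec.therapy.basal_dose == 24.0
        assert rec.flagged  # 24/18 - 1 = +33%

    def test_identity_recommendation_unflagged(self):
        prev = self._prev()
        rec = finalize(prev, prev, prev)
        assert rec.therapy.titratable() == prev.titratable()
        assert not rec.flagged

    def test_rounding_stays_inside_cap_window(self):
        prev = self._prev()  # basal 20, window [16, 24]
        want = prev.with_basal(23.8)  # would round to 24 (inside)
        assert finalize(want, prev, prev).therapy.basal_dose == 24.0
        prev19 = prev.with_basal(19.0)  # window [15.2, 22.8]
        want19 = prev19.with_basal(22.8)  # rounds to 23, outside -> 22
        assert finalize(want19, prev19, prev19).therapy.basal_dose == 22.0

    def test_never_zeroes_a_positive_dose(self):
        prev = g.TherapyParameters(
            basal_dose=1.0, meal_strategy="fixed_dose",
            fixed_dose={"breakfast": 0.5, "lunch": 0.5, "dinner": 0.5},
            basal_increment=1.0, bolus_increment=0.5,
        )
        want = prev.with_basal(0.5).with_prandial("lunch", 0.1)
        rec = finalize(want, prev, prev)
        assert rec.therapy.basal_dose > 0
        assert rec.therapy.fixed_dose["lunch"] > 0


class TestFit:
    def test_noiseless_self_consistency(self, base, cc_therapy):
        """Data generated at the prior median recover it almost exactly."""
        week = build_logged_week(base, cc_therapy, noise_sd=0.0)
        state = TitrationState.initial(cc_therapy, base)
        fit = fit_patient_model(week, state, cc_therapy, base)
        assert fit.r2 >= 0.999
        np.testing.assert_allclose(
            np.exp(fit.log_map), np.exp(state.prior_log_median), rtol=1e-3
        )

    def test_pure_noise_gives_zero_blend_weight(self, base, cc_therapy):
        """Structureless CGM: R^2 ~ 0, so the blend keeps the incumbent."""
        rng = np.random.default_rng(8)
        times = np.arange(0, 7 * 1440, 15.0)
        glucose = 9.0 + rng.normal(0, 2.0, len(times))
        log = EventLog()
        for d in range(7):
            log.append(DoseEvent(timestamp=d * 1440 + 750.0, kind=EventKind.meal_bolus,
                                 delivered=6.0, carbs=60.0, meal_type="lunch"))
        week = WeekData(CgmTrace(times, glucose, np.zeros(len(times), int)), log, 0)
        state = TitrationState.initial(cc_therapy, base)
        fit = fit_patient_model(week, state, cc_therapy, base)
        assert fit.r2 <= 0.1
        star = optimal_therapy(fit, cc_therapy, week, base)
        out, w = blend(star, cc_therapy, fit)
        assert max(w.values()) <= 0.1
        assert out.basal_dose == pytest.approx(cc_therapy.basal_dose, rel=0.02)

    def test_insufficient_data_raises(self, base, cc_therapy):
        times = np.arange(0, 1440, 15.0)  # one day only
        week = WeekData(
            CgmTrace(times, np.full(len(times), 8.0), np.zeros(len(times), int)),
            EventLog(), 0,
        )
        with pytest.raises(g.FitFailure):
            fit_patient_model(week, TitrationState.initial(cc_therapy, base), cc_therapy, base)


class TestOptimalTherapy:
    def test_underbasalized_patient_gets_more_basal(self, base, cc_therapy):
        """Fasting hyperglycemia pushes the closed-form basal upward."""
        low = cc_therapy.with_basal(10.0)
        week = build_logged_week(base, low, noise_sd=0.0)
        state = TitrationState.initial(low, base)
        fit = fit_patient_model(week, state, low, base)
        star = optimal_therapy(fit, low, week, base)
        assert star.basal_dose > low.basal_dose

    def test_overbolused_breakfast_reduced(self, base):
        """Post-breakfast hypoglycemia pulls the breakfast parameter down."""
        therapy = g.TherapyParameters(
            basal_dose=35.0, meal_strategy="carb_counting",
            carb_ratio={"breakfast": 3.0, "lunch": 10.0, "dinner": 10.0},
            glucose_target=6.0,
        )
        week = build_logged_week(base, therapy, noise_sd=0.0)
        state = TitrationState.initial(therapy, base)
        fit = fit_patient_model(week, state, therapy, base)
        star = optimal_therapy(fit, therapy, week, base)
        assert star.prandial_insulin_equivalent("breakfast") < 1 / 3.0


class TestTitrateWeek:
    def test_well_controlled_week_barely_moves(self, base):
        """Therapy at the engine's own optimum is a fixed point (< 3% move)."""
        start = g.TherapyParameters(
            basal_dose=round(g.steady_state_basal(base, 6.0)),
            meal_strategy="carb_counting",
            carb_ratio={"breakfast": 8.0, "lunch": 8.0, "dinner": 8.0},
            glucose_target=6.0,
        )
        week = build_logged_week(base, start, noise_sd=0.0)
        state = TitrationState.initial(start, base)
        fit = fit_patient_model(week, state, start, base)
        star = optimal_therapy(fit, start, week, base)
        # adopt the optimum (display-rounded) and live a week on it
        therapy = g.TherapyParameters(
            basal_dose=round(star.basal_dose), meal_strategy="carb_counting",
            carb_ratio={m: round(star.carb_ratio[m], 1) for m in star.carb_ratio},
            glucose_target=6.0,
        )
        week2 = build_logged_week(base, therapy, noise_sd=0.0)
        rec, _ = titrate_week(week2, therapy, TitrationState.initial(therapy, base), base)
        prev, new = therapy.titratable(), rec.therapy.titratable()
        for k in prev:
            assert abs(new[k] / prev[k] - 1) < 0.03

    def test_empty_week_leaves_therapy_unchanged(self, base, cc_therapy):
        week = WeekData(
            CgmTrace(np.array([0.0]), np.array([8.0]), np.array([0])), EventLog(), 0
        )
        state = TitrationState.initial(cc_therapy, base)
        rec, new_state = titrate_week(week, cc_therapy, state, base)
        assert rec.therapy.titratable() == cc_therapy.titratable()
        assert not rec.flagged
        assert "no change" in rec.rationale
        assert new_state.week == 1

    def test_cap_always_respected(self, base, cc_therapy):
        """Every recommended parameter sits within +/-20% of its predecessor."""
        low = cc_therapy.with_basal(12.0)
        week = build_logged_week(base, low, noise_sd=0.3, rng=np.random.default_rng(5))
        state = TitrationState.initial(low, base)
        rec, _ = titrate_week(week, low, state, base)
        prev, new = low.titratable(), rec.therapy.titratable()
        for k in prev:
            assert 0.8 - 1e-9 <= new[k] / prev[k] <= 1.2 + 1e-9
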