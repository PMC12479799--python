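"""Bolus calculator: IOB, trend arrows, dose formulas, alerts, lifecycle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glucodss.bolus import (
    MissingGlucose,
    correction_bolus,
    default_meal_type,
    insulin_on_board,
    meal_bolus,
    trend_adjusted_glucose,
    update_alerts,
)
from glucodss.core import InvalidArgument
from glucodss.events import DoseEvent, EventKind, EventLog, NotFound


def _ev(t_min, units, kind=EventKind.meal_bolus):
    return DoseEvent(timestamp=float(t_min), kind=kind, delivered=units)


class TestInsulinOnBoard:
    @pytest.mark.parametrize(
        "events,now_h,expected",
        [
            ([(0, 6.0)], 2.0, 3.0),  # midpoint of linear decay
            ([(0, 6.0)], 5.0, 0.0),  # fully decayed
            ([(0, 4.0), (60, 2.0)], 2.0, 3.5),  # 4*0.5 + 2*0.75
            ([], 1.0, 0.0),
        ],
    )
    def test_examples(self, events, now_h, expected):
        evs = [_ev(t, u) for t, u in events]
        assert insulin_on_board(evs, now_h * 60, 4.0) == pytest.approx(expected)

    def test_basal_excluded(self):
        evs = [_ev(0, 6.0), _ev(0, 30.0, EventKind.basal)]
        assert insulin_on_board(evs, 120, 4.0) == pytest.approx(3.0)

    @given(
        doses=st.lists(
            st.tuples(st.integers(0, 600), st.floats(0.5, 15)), min_size=0, max_size=12
        ),
        now=st.integers(0, 900),
        ait=st.sampled_from([2.0, 4.0, 6.0]),
    )
    @settings(max_examples=150, deadline=None)
    def test_matches_per_event_decay_oracle(self, doses, now, ait):
        """Closed-form IOB equals an independent per-event decay sum."""
        evs = [_ev(t, u) for t, u in doses]
        expected = 0.0
        for t, u in doses:
            elapsed = now - t
            if 0 <= elapsed < ait * 60:
                expected += u * (1 - elapsed / (ait * 60))
        assert insulin_on_board(evs, now, ait) == pytest.approx(expected, abs=1e-9)


class TestTrendArrows:
    @pytest.mark.parametrize(
        "glucose,arrow,expected",
        [
            (8.0, "stable", 8.0),
            (8.0, "rising_fast", 10.8),
            (8.0, "rising", 9.4),
            (8.0, "falling", 6.6),
            (1.0, "falling_fast", 0.1),  # floor rule
        ],
    )
    def test_offsets(self, glucose, arrow, expected):
        assert trend_adjusted_glucose(glucose, arrow) == pytest.approx(expected)

    def test_unknown_arrow(self):
        with pytest.raises(InvalidArgument):
            trend_adjusted_glucose(8.0, "sideways")


class TestMealBolus:
    def test_carb_counting_with_iob(self, cc_therapy):
        # food 60/10=6, correction (10-5.5)/2=2.25, IOB 1 applied to correction
        events = [_ev(0, 2.0)]  # 2 U at t=0, AIT 4 h -> IOB 1.0 at t=2 h
        dose, bd = meal_bolus(cc_therapy, "lunch", 60, 10.0, "stable", events, 120)
        assert bd.raw_total == pytest.approx(7.25)
        assert dose == pytest.approx(7.0)  # tie rounds down at 0.5-U pen

    def test_null_case(self, cc_therapy):
        dose, _ = meal_bolus(cc_therapy, "lunch", 0, 5.5, "stable", [], 0)
        assert dose == 0.0

    def test_negative_correction_reduces_fixed_dose(self, fd_therapy):
        dose, bd = meal_bolus(fd_therapy, "dinner", None, 4.0, "stable", [], 0)
        assert bd.raw_total == pytest.approx(7.0 - 0.75)
        assert dose == pytest.approx(6.0)

    def test_iob_never_eats_food_component(self, cc_therapy):
        # glucose below target: correction negative, big IOB must not apply
        events = [_ev(0, 8.0)]
        dose, bd = meal_bolus(cc_therapy, "lunch", 60, 4.5, "stable", events, 60)
        assert bd.iob_applied == 0.0
        assert bd.raw_total == pytest.approx(6.0 - 0.5)

    def test_requires_glucose(self, cc_therapy):
        with pytest.raises(MissingGlucose):
            meal_bolus(cc_therapy, "lunch", 60, None, "stable", [], 0)

    def test_monotonicity_and_increment(self, cc_therapy):
        """Dose is nondecreasing in carbs and glucose, nonincreasing in IOB,
        and always a nonnegative multiple of the pen increment."""
        rng = np.random.default_rng(11)
        prev_events = [_ev(0, 3.0)]
        for _ in range(150):
            carbs = rng.uniform(0, 120)
            glucose = rng.uniform(3, 20)
            d0, _ = meal_bolus(cc_therapy, "lunch", carbs, glucose, "stable", prev_events, 60)
            d_carbs, _ = meal_bolus(cc_therapy, "lunch", carbs + 15, glucose, "stable", prev_events, 60)
            d_gluc, _ = meal_bolus(cc_therapy, "lunch", carbs, glucose + 2, "stable", prev_events, 60)
            d_iob, _ = meal_bolus(cc_therapy, "lunch", carbs, glucose, "stable", [_ev(0, 6.0)], 60)
            assert d_carbs >= d0
            assert d_gluc >= d0
            assert d_iob <= d0 + 1e-9  # larger IOB never raises the dose
            for d in (d0, d_carbs, d_gluc, d_iob):
                assert d >= 0
                assert (d / cc_therapy.bolus_increment) == pytest.approx(
                    round(d / cc_therapy.bolus_increment)
                )

    def test_override_annotation_never_changes_dose(self, cc_therapy):
        """Override reasons are notes; recomputation ignores them."""
        ev = DoseEvent(
            timestamp=0.0, kind=EventKind.meal_bolus, delivered=4.0,
            recommended=6.0, override_reason="exercise",
        )
        assert ev.overridden
        d1, _ = meal_bolus(cc_therapy, "lunch", 60, 10.0, "stable", [ev], 120)
        ev_plain = _ev(0, 4.0)
        d2, _ = meal_bolus(cc_therapy, "lunch", 60, 10.0, "stable", [ev_plain], 120)
        assert d1 == d2


class TestCorrectionBolus:
    @pytest.mark.parametrize(
        "glucose,iob,expected",
        [(14.0, 0.0, 4.0), (6.0, 0.0, 0.0), (9.0, 5.0, 0.0)],
    )
    def test_examples(self, glucose, iob, expected):
        import glucodss as g

        therapy = g.TherapyParameters(
            basal_dose=20, meal_strategy="fixed_dose",
            fixed_dose={"breakfast": 5, "lunch": 5, "dinner": 5},
            isf=2.0, glucose_target=6.0, bolus_increment=0.5,
        )
        events = [_ev(0, iob * 2)] if iob else []  # half-decayed at 2 h
        dose, _ = correction_bolus(therapy, glucose, "stable", events, 120)
        assert dose == pytest.approx(expected)


class TestMealTypeDefaults:
    @pytest.mark.parametrize(
        "hour,expected",
        [(7.5, "breakfast"), (12.0, "lunch"), (16.0, "dinner"),
         (22.25, "bedtime"), (3.0, "bedtime"), (5.0, "breakfast"),
         (10.99, "breakfast"), (11.0, "lunch"), (20.99, "dinner"), (21.0, "bedtime")],
    )
    def test_windows(self, hour, expected):
        assert default_meal_type(hour) == expected


class TestAlerts:
    def _daily_log(self, days, basal_days, entries_per_day=5):
        log = EventLog()
        for d in range(days):
            t0 = d * 1440
            for k in range(entries_per_day):
                log.append(_ev(t0 + 8 * 60 + k * 120, 3.0))
            if d in basal_days:
                log.append(_ev(t0 + 21 * 60, 20.0, EventKind.basal))
        return log

    def test_adherent_user_no_alerts(self):
        log = self._daily_log(5, basal_days=range(5))
        state = update_alerts(log, 5 * 1440.0)
        assert state.active_alerts == set()

    def test_missed_basal_streak(self):
        log = self._daily_log(5, basal_days=[0, 1])  # days 2,3,4 missed
        state = update_alerts(log, 5 * 1440.0)
        assert state.missed_basal_streak == 3
        assert "missed_basal" in state.active_alerts
        # two missed days do not fire
        log2 = self._daily_log(4, basal_days=[0, 1])
        assert "missed_basal" not in update_alerts(log2, 4 * 1440.0).active_alerts

    def test_insufficient_use_boundary(self):
        log = EventLog()
        now = 3 * 1440.0
        for k in range(3):
            log.append(_ev(now - 600 - k * 100, 2.0))
        state = update_alerts(log, now)
        assert state.entries_last_36h == 3
        assert "insufficient_use" in state.active_alerts
        log.append(_ev(now - 60, 2.0))
        assert "insufficient_use" not in update_alerts(log, now).active_alerts

    def test_alert_clears_when_condition_resolves(self):
        log = self._daily_log(5, basal_days=[0, 1])
        assert "missed_basal" in update_alerts(log, 5 * 1440.0).active_alerts
        log.append(_ev(5 * 1440 + 60, 20.0, EventKind.basal))
        assert "missed_basal" not in update_alerts(log, 6 * 1440.0).active_alerts


class TestDeletionWindow:
    def test_lifecycle(self):
        log = EventLog()
        ev = log.append(_ev(100, 4.0))
        assert log.delete_entry(ev.event_id, 110.0) is True  # +10 min
        assert len(log) == 0
        ev2 = log.append(_ev(200, 4.0))
        assert log.delete_entry(ev2.event_id, 231.01) is False  # +31 min refused
        assert len(log) == 1
        with pytest.raises(NotFound):
            log.delete_entry(ev.event_id, 120.0)  # already deleted
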