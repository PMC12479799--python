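"""Shared fixtures.

The default in-silico trial (84 participants, 12 weeks, seeds from the
default config) is expensive, so it is generated once per session and
shared by the acceptance-level tests that audit it.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings as hyp_settings

import glucodss as g
from glucodss.config import default_config

hyp_settings.register_profile("repro", derandomize=True, deadline=None)
hyp_settings.load_profile("repro")


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture()
def cc_therapy():
    """A representative carb-counting prescription."""
    return g.TherapyParameters(
        basal_dose=20.0,
        meal_strategy="carb_counting",
        carb_ratio={"breakfast": 10.0, "lunch": 10.0, "dinner": 10.0},
        isf=2.0,
        glucose_target=5.5,
        active_insulin_time=4.0,
        basal_increment=1.0,
        bolus_increment=0.5,
    )


@pytest.fixture()
def fd_therapy():
    """A representative fixed-dose prescription."""
    return g.TherapyParameters(
        basal_dose=18.0,
        meal_strategy="fixed_dose",
        fixed_dose={"breakfast": 5.0, "lunch": 6.0, "dinner": 7.0},
        isf=2.0,
        glucose_target=5.5,
        active_insulin_time=4.0,
        basal_increment=1.0,
        bolus_increment=0.5,
    )


@pytest.fixture(scope="session")
def default_cohort(cfg):
    """The default 84-participant cohort at the config seed."""
    return g.generate_cohort(cfg.trial.n_participants, cfg.trial.seed, cfg)


@pytest.fixture(scope="session")
def default_trial(cfg, default_cohort):
    """The default two-arm 12-week trial run."""
    return g.run_trial(
        default_cohort, weeks=cfg.trial.weeks, seed=cfg.trial.seed + 1, cfg=cfg
    )


from glucodss.trial import build_logged_week  # noqa: E402  (re-export for tests)
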