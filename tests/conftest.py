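"""Shared fixtures: small deterministic sessions and feature tables.

Heavy objects (simulated sessions, feature tables) are session-scoped so the
whole suite pays for them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from whiskloc.config import SessionConfig
from whiskloc.features import build_feature_table
from whiskloc.session import (GO, LICK, NO_LICK, NOGO, Session, TouchEvent,
                              Trial, outcome_of)
from whiskloc.synth import generate_session

RECOVERY_SEEDS = tuple(range(1, 11))


@pytest.fixture(scope="session")
def default_session():
    """One mid-sized default-parameter session used by many read-only tests."""
    return generate_session(SessionConfig(n_trials=120, rng_seed=11))


@pytest.fixture(scope="session")
def default_table(default_session):
    return build_feature_table(default_session)


@pytest.fixture(scope="session")
def recovery_sessions():
    """Ten 200-trial sessions with seeds 1-10 for parameter-recovery checks."""
    return [generate_session(SessionConfig(n_trials=200, rng_seed=s))
            for s in RECOVERY_SEEDS]


@pytest.fixture(scope="session")
def recovery_tables(recovery_sessions):
    return [build_feature_table(s) for s in recovery_sessions]


def make_toy_trial(trial_id=0, pole_position=3.0, trial_type=GO, choice=NO_LICK,
                   n_samples=4000, touch_events=(), lick_times=(),
                   angle_value=0.0):
    angle = np.full(n_samples, float(angle_value))
    return Trial(
        trial_id=trial_id,
        pole_position=pole_position,
        trial_type=trial_type,
        angle_series=angle,
        curvature_series=np.zeros(n_samples),
        follicle_series=np.zeros((n_samples, 2)),
        touch_events=list(touch_events),
        lick_times=list(lick_times),
        choice=choice,
        outcome=outcome_of(trial_type, choice),
    )


def make_touch(onset, direction="protraction", **kw):
    defaults = dict(angle_at_touch=20.0, phase_at_touch=0.0,
                    amplitude_at_touch=15.0, midpoint_at_touch=10.0,
                    curvature_pre=0.02, radial_distance=9.0)
    defaults.update(kw)
    return TouchEvent(onset=float(onset), direction=direction, **defaults)


@pytest.fixture
def toy_config():
    """Config with the pole at trial start so the answer period is 1250-2000
    ms absolute — convenient for hand-built trials."""
    return SessionConfig(n_trials=4, pole_trigger_time=0.0,
                         sampling_period=(0.0, 750.0),
                         answer_period=(1250.0, 2000.0))


def make_toy_session(config, trials):
    return Session(config=config, trials=list(trials))
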