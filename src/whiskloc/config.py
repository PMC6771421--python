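"""Session and run configuration.

A :class:`SessionConfig` fully determines a synthetic go/no-go localization
session: trial timing, pole geometry, whisking motor statistics, and the
ground-truth choice rule. All randomness derives from ``rng_seed`` through
per-trial child streams, so a config is a complete recipe for a session.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
import yaml

TASK_VARIANTS = ("anteroposterior", "angle", "distance")
CHOICE_FEATURES = ("midpoint", "angle")


class ConfigurationError(ValueError):
    """Raised when a session or run configuration is internally inconsistent."""


@dataclass
class SessionConfig:
    """Parameters of a synthetic localization session.

    Times are milliseconds, positions millimetres, angles degrees.
    ``sampling_period`` and ``answer_period`` are intervals relative to pole
    onset (``pole_trigger_time``). Go positions are posterior (0-5 mm),
    no-go anterior (5-10 mm); their shared border is the discrimination
    boundary.
    """

    n_trials: int = 200
    sample_rate: float = 1000.0
    trial_duration: float = 4000.0
    pole_trigger_time: float = 500.0
    pole_rise_duration: float = 200.0
    sampling_period: Tuple[float, float] = (0.0, 750.0)
    answer_period: Tuple[float, float] = (1250.0, 2000.0)
    go_range: Tuple[float, float] = (0.0, 5.0)
    nogo_range: Tuple[float, float] = (5.0, 10.0)
    lateral_offset: float = 8.0
    follicle_rest: Tuple[float, float] = (0.0, 0.0)
    whisking_freq: float = 15.0
    whisk_period_cv: float = 0.12
    protraction_noise_sd: float = 10.9
    cue_onset_latency_mean: float = 60.0
    cue_onset_latency_sd: float = 16.0
    # motor-plan internals
    rest_angle: float = -15.0
    quiescent_amplitude: float = 0.8
    amplitude_mean: float = 20.0
    amplitude_clip: Tuple[float, float] = (5.5, 40.0)
    midpoint_ou_sd: float = 9.0
    midpoint_ou_rho: float = 0.9
    whisks_before_stop_mean: float = 2.5
    touch_adaptation_factor: float = 2.6
    # follicle / curvature proxies
    follicle_excursion: float = 1.5
    follicle_direction: Tuple[float, float] = (1.3, 0.7)
    curvature_base: float = 0.02
    curvature_slope: float = 5e-4
    curvature_noise_sd: float = 2e-3
    curvature_contact_gain: float = 1e-3
    # ground-truth choice rule: weights on (kinematic feature, touch count) + bias
    choice_weights: Tuple[float, float, float] = (-3.0, 2.5, -0.75)
    choice_feature: str = "midpoint"
    # reference normalization used by the generative rule (mean, scale)
    choice_midpoint_ref: Tuple[float, float] = (12.0, 10.0)
    choice_angle_ref: Tuple[float, float] = (32.0, 10.0)
    choice_count_ref: Tuple[float, float] = (2.5, 5.0)
    # lick motor parameters
    lick_delay_shape: float = 2.0
    lick_delay_scale: float = 100.0
    lick_interval: float = 130.0
    early_lick_prob: float = 0.15
    task_variant: str = "anteroposterior"
    # angle-variant span (degrees) and distance-variant go/no-go ranges (mm)
    distance_go_range: Tuple[float, float] = (8.0, 10.0)
    distance_nogo_range: Tuple[float, float] = (10.0, 13.0)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- derived geometry -------------------------------------------------
    @property
    def boundary_position(self) -> float:
        """Anteroposterior discrimination boundary (mm)."""
        return self.go_range[1]

    @property
    def pole_onset(self) -> float:
        return self.pole_trigger_time

    @property
    def pole_reach_time(self) -> float:
        """Absolute time at which the rising pole enters whisker reach."""
        return self.pole_trigger_time + self.pole_rise_duration

    @property
    def pole_down_time(self) -> float:
        """Absolute time at which the pole leaves reach (end of answer period)."""
        return self.pole_trigger_time + self.answer_period[1]

    @property
    def answer_window(self) -> Tuple[float, float]:
        """Absolute answer-period interval."""
        return (
            self.pole_trigger_time + self.answer_period[0],
            self.pole_trigger_time + self.answer_period[1],
        )

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_duration * self.sample_rate / 1000.0))

    def validate(self) -> None:
        if self.sample_rate <= 0:
            raise ConfigurationError("sample_rate must be positive")
        if self.trial_duration <= 0:
            raise ConfigurationError("trial_duration must be positive")
        if self.n_trials < 1:
            raise ConfigurationError("n_trials must be >= 1")
        if self.task_variant not in TASK_VARIANTS:
            raise ConfigurationError(
                f"task_variant must be one of {TASK_VARIANTS}, got {self.task_variant!r}"
            )
        if self.choice_feature not in CHOICE_FEATURES:
            raise ConfigurationError(
                f"choice_feature must be one of {CHOICE_FEATURES}, got {self.choice_feature!r}"
            )
        if not self.go_range[1] == self.nogo_range[0]:
            raise ConfigurationError(
                "go_range and nogo_range must be contiguous: the shared border "
                "is the discrimination boundary"
            )
        if self.go_range[0] >= self.go_range[1] or self.nogo_range[0] >= self.nogo_range[1]:
            raise ConfigurationError("position ranges must be non-empty intervals")
        if self.sampling_period[1] > self.answer_period[0]:
            raise ConfigurationError("sampling_period must end before answer_period begins")
        # the whisking frequency must sit strictly inside the 6-60 Hz band that
        # the kinematic decomposition assumes
        if not 6.0 < self.whisking_freq < 60.0:
            raise ConfigurationError("whisking_freq must lie strictly inside (6, 60) Hz")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key, value in d.items():
            if isinstance(value, tuple):
                d[key] = list(value)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SessionConfig":
        known = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for key, value in d.items():
            if key not in known:
                raise ConfigurationError(f"unknown session config key: {key!r}")
            if isinstance(value, list):
                value = tuple(value)
            kwargs[key] = value
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "SessionConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def seed_sequence(self) -> np.random.SeedSequence:
        return np.random.SeedSequence(self.rng_seed)
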