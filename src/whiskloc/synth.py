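"""Synthetic go/no-go localization sessions with full ground truth.

The generator emulates the motor and task statistics the downstream analysis
assumes: cue-triggered whisking onset with ~60 ms latency, whisking built as
``midpoint(t) + amplitude(t) * cos(phase(t))`` with a slowly drifting (AR-1)
midpoint, per-whisk peak protraction targeted at the go/no-go discrimination
boundary with large (10.9 deg SD) whisk-to-whisk noise, touch-adaptive
prolongation of the whisking bout, geometric touch detection against a pole
over contiguous go (posterior) / no-go (anterior) position ranges, and
choices drawn from a known generative logistic rule on whisking midpoint at
touch plus touch count.

Every latent (true midpoint/amplitude/phase series, whisk schedule, choice
probability) is returned with the trial so that decomposition, feature
extraction and classifier fitting can be tested as parameter recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .config import ConfigurationError, SessionConfig
from .session import (GO, LICK, NO_LICK, NOGO, PROTRACTION, RETRACTION,
                      Session, TouchEvent, Trial, outcome_of)

__all__ = [
    "generate_whisking_trace",
    "generate_touches",
    "generate_choice",
    "choice_probability",
    "generate_trial",
    "generate_session",
    "pole_xy",
    "pole_angle_at_rest",
    "boundary_angle",
    "follicle_from_angle",
    "TouchResult",
]

_ENVELOPE_SMOOTH_MS = 8.0
_AMPLITUDE_DECAY_MS = 150.0
_MIDPOINT_DECAY_MS = 250.0
_FOLLICLE_ANGLE_SPAN = 50.0  # deg of protraction producing the full excursion


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def pole_xy(position: float, config: SessionConfig) -> np.ndarray:
    """World coordinates (mm) of the pole for a trial's position parameter.

    ``position`` is mm along the anteroposterior axis for the default task,
    azimuth in degrees for the angle variant, and radial distance in mm for
    the distance variant (both variants pivot about the boundary geometry).
    """
    fx, fy = config.follicle_rest
    if config.task_variant == "anteroposterior":
        return np.array([fx + position, fy + config.lateral_offset])
    bx = config.boundary_position
    r_b = math.hypot(bx, config.lateral_offset)
    if config.task_variant == "angle":
        psi = math.radians(position)
        return np.array([fx + r_b * math.sin(psi), fy + r_b * math.cos(psi)])
    # distance variant: azimuth fixed at the boundary angle
    theta_b = math.atan2(bx, config.lateral_offset)
    return np.array([fx + position * math.sin(theta_b),
                     fy + position * math.cos(theta_b)])


def pole_angle_at_rest(position: float, config: SessionConfig) -> float:
    """Azimuthal angle (deg) of the pole as seen from the resting follicle."""
    px, py = pole_xy(position, config)
    fx, fy = config.follicle_rest
    return math.degrees(math.atan2(px - fx, py - fy))


def boundary_angle(config: SessionConfig) -> float:
    """Azimuthal angle (deg) of the discrimination boundary from the resting
    follicle. The boundary is defined by the anteroposterior task geometry in
    every task variant (the variants pivot about it)."""
    return math.degrees(math.atan2(config.boundary_position,
                                   config.lateral_offset))


def follicle_from_angle(angle_series: np.ndarray, config: SessionConfig) -> np.ndarray:
    """Follicle trajectory as an affine function of the instantaneous angle.

    The follicle translates along a fixed direction, reaching the configured
    total excursion over a nominal protraction span.
    """
    direction = np.asarray(config.follicle_direction, dtype=float)
    norm = np.linalg.norm(direction)
    if norm == 0 or config.follicle_excursion == 0:
        return np.tile(np.asarray(config.follicle_rest, dtype=float),
                       (len(angle_series), 1))
    unit = direction / norm
    gain = config.follicle_excursion / _FOLLICLE_ANGLE_SPAN
    protraction = np.asarray(angle_series, dtype=float) - config.rest_angle
    offsets = gain * protraction[:, None] * unit[None, :]
    return np.asarray(config.follicle_rest, dtype=float)[None, :] + offsets


# ---------------------------------------------------------------------------
# whisking trace
# ---------------------------------------------------------------------------

def generate_whisking_trace(
    config: SessionConfig,
    rng: np.random.Generator,
    pole_angle: Optional[float] = None,
) -> Tuple[np.ndarray, dict]:
    """Generate one trial's whisker angle series plus latent ground truth.

    Before the cue the whisker sits near ``rest_angle`` with sub-threshold
    oscillation. After cue + latency, whisk cycles advance at approximately
    ``whisking_freq`` with per-whisk period jitter; each whisk's peak
    protraction targets the discrimination boundary with Gaussian noise of
    ``protraction_noise_sd``. The slow component of that noise lives in the
    AR-1 midpoint, the rest in the per-whisk amplitude.

    If ``pole_angle`` is given, whisks whose peak target reaches it while the
    pole is in reach count as predicted touches, and the first one extends
    the whisking bout by the touch-adaptation factor.

    Returns ``(angle_series, latent)`` where ``latent`` holds the true
    midpoint/amplitude/phase series, the whisk schedule, and bookkeeping.
    """
    if config.sample_rate <= 0 or config.trial_duration <= 0:
        raise ConfigurationError("sample_rate and trial_duration must be positive")
    n = config.n_samples
    dt = 1000.0 / config.sample_rate
    t = np.arange(n) * dt

    latency = max(0.0, rng.normal(config.cue_onset_latency_mean,
                                  config.cue_onset_latency_sd))
    cue = config.pole_trigger_time + latency
    theta_b = boundary_angle(config)

    t_nom = 1000.0 / config.whisking_freq
    sigma_m = config.midpoint_ou_sd
    sigma_a = math.sqrt(max(config.protraction_noise_sd ** 2 - sigma_m ** 2, 0.0))
    m_base = theta_b - config.amplitude_mean
    rho = config.midpoint_ou_rho

    n_base = 1 + int(rng.poisson(max(config.whisks_before_stop_mean - 1.0, 0.0)))
    n_post = max(1, int(round(config.touch_adaptation_factor
                              * (1 + rng.poisson(max(config.whisks_before_stop_mean - 1.0, 0.0))))))

    reach, down = config.pole_reach_time, config.pole_down_time

    troughs: List[float] = []
    peaks: List[float] = []
    periods: List[float] = []
    amps: List[float] = []
    mids: List[float] = []
    ou = sigma_m * rng.standard_normal() if sigma_m > 0 else 0.0
    first_touch_whisk = -1
    first_reach_whisk: Optional[int] = None
    tau = cue
    k = 0
    while tau < config.trial_duration:
        period = t_nom * float(np.clip(1.0 + rng.normal(0.0, config.whisk_period_cv),
                                       0.6, 1.6))
        peak = tau + period / 2.0
        amp = float(np.clip(config.amplitude_mean + sigma_a * rng.standard_normal(),
                            config.amplitude_clip[0], config.amplitude_clip[1]))
        mid = m_base + ou
        troughs.append(tau)
        peaks.append(peak)
        periods.append(period)
        amps.append(amp)
        mids.append(mid)
        if first_reach_whisk is None and peak >= reach:
            first_reach_whisk = k
        if (pole_angle is not None and first_touch_whisk < 0
                and mid + amp >= pole_angle and reach <= peak <= down):
            first_touch_whisk = k
        # bout termination: adaptive extension after the first (predicted) touch
        if first_touch_whisk >= 0:
            if k >= first_touch_whisk + n_post:
                break
        elif first_reach_whisk is not None and k >= first_reach_whisk + n_base:
            break
        ou = rho * ou + sigma_m * math.sqrt(1.0 - rho ** 2) * rng.standard_normal() \
            if sigma_m > 0 else 0.0
        tau += period
        k += 1

    troughs_a = np.asarray(troughs)
    peaks_a = np.asarray(peaks)
    periods_a = np.asarray(periods)
    end_trough = troughs_a[-1] + periods_a[-1] if len(troughs) else cue

    # --- phase: -pi at troughs, 0 at peaks, advancing at the whisk rate ----
    phase = np.empty(n)
    pre = t < cue
    phase[pre] = -math.pi + 2.0 * math.pi * config.whisking_freq * (t[pre] - cue) / 1000.0
    for tau_k, period in zip(troughs, periods):
        seg = (t >= tau_k) & (t < tau_k + period)
        phase[seg] = -math.pi + 2.0 * math.pi * (t[seg] - tau_k) / period
    post = t >= end_trough
    phase[post] = -math.pi + 2.0 * math.pi * config.whisking_freq * (t[post] - end_trough) / 1000.0
    phase = np.mod(phase + math.pi, 2.0 * math.pi) - math.pi

    # --- envelopes through per-whisk control points ------------------------
    def envelope(points_t, points_v, quiet_value, decay):
        ts = [0.0, max(cue - 10.0, 0.0)]
        vs = [quiet_value, quiet_value]
        ts.extend(points_t)
        vs.extend(points_v)
        ts.extend([end_trough + decay, config.trial_duration])
        vs.extend([quiet_value, quiet_value])
        ts = np.maximum.accumulate(np.asarray(ts))
        env = np.interp(t, ts, np.asarray(vs))
        if _ENVELOPE_SMOOTH_MS > 0:
            env = gaussian_filter1d(env, _ENVELOPE_SMOOTH_MS / dt, mode="nearest")
        return env

    amp_env = np.maximum(
        envelope(list(peaks_a), amps, config.quiescent_amplitude, _AMPLITUDE_DECAY_MS),
        0.0)
    mid_env = envelope(list(peaks_a), mids, config.rest_angle, _MIDPOINT_DECAY_MS)

    angle = mid_env + amp_env * np.cos(phase)

    latent = {
        "midpoint": mid_env,
        "amplitude": amp_env,
        "phase": phase,
        "cue_time": cue,
        "whisk_peak_times": peaks_a,
        "whisk_trough_times": troughs_a,
        "whisk_peak_targets": np.asarray(mids) + np.asarray(amps),
        "first_touch_whisk": float(first_touch_whisk),
    }
    return angle, latent


# ---------------------------------------------------------------------------
# touches
# ---------------------------------------------------------------------------

@dataclass
class TouchResult:
    events: List[TouchEvent]
    clipped_angle: np.ndarray
    follicle: np.ndarray
    curvature: np.ndarray
    pole_angle: np.ndarray


def generate_touches(
    angle_series: np.ndarray,
    follicle_series: np.ndarray,
    pole_position: float,
    config: SessionConfig,
    latent: Optional[dict] = None,
    rng: Optional[np.random.Generator] = None,
) -> TouchResult:
    """Detect whisker-pole contacts geometrically and clip the angle at the pole.

    A protraction touch fires at each upward crossing of the (follicle-
    dependent) pole angle while the pole is in reach; the contact's ending
    downward crossing fires a retraction touch. If the pole comes into reach
    with the whisker already past it, the contact opens without a protraction
    onset and only the retraction event is emitted. During contact the angle
    is clipped at the pole (the pole blocks further protraction).

    The curvature trace is a monotone linear function of protraction angle
    plus smoothed Gaussian noise, with a contact-induced increment
    proportional to the blocked protraction. An unreachable pole yields an
    empty event list.
    """
    angle = np.asarray(angle_series, dtype=float)
    n = angle.size
    dt = 1000.0 / config.sample_rate
    t = np.arange(n) * dt
    pxy = pole_xy(pole_position, config)

    def pole_angle_from(follicle: np.ndarray) -> np.ndarray:
        dx = pxy[0] - follicle[:, 0]
        dy = pxy[1] - follicle[:, 1]
        return np.degrees(np.arctan2(dx, dy))

    # two-pass clipping: the follicle translates with the (clipped) angle
    theta_pole = pole_angle_from(np.asarray(follicle_series, dtype=float))
    available = (t >= config.pole_reach_time) & (t < config.pole_down_time)
    clipped = np.where(available & (angle > theta_pole), theta_pole, angle)
    follicle = follicle_from_angle(clipped, config)
    theta_pole = pole_angle_from(follicle)
    clipped = np.where(available & (angle > theta_pole), theta_pole, angle)

    # curvature proxy from the realized (clipped) angle
    if rng is None:
        rng = np.random.default_rng(0)
    noise = gaussian_filter1d(rng.normal(0.0, config.curvature_noise_sd, n),
                              max(_ENVELOPE_SMOOTH_MS / dt, 1.0), mode="nearest")
    blocked = np.where(available, np.maximum(angle - theta_pole, 0.0), 0.0)
    curvature = (config.curvature_base
                 + config.curvature_slope * (clipped - config.rest_angle)
                 + noise
                 + config.curvature_contact_gain * blocked)

    above = available & (angle >= theta_pole)
    events: List[TouchEvent] = []

    def snapshot(idx: int, direction: str) -> TouchEvent:
        pre_idx = max(idx - 1, 0)  # one sample (1 ms at 1 kHz) before onset
        radial = float(np.hypot(pxy[0] - follicle[idx, 0], pxy[1] - follicle[idx, 1]))
        if latent is not None:
            ph = float(latent["phase"][idx])
            am = float(latent["amplitude"][idx])
            mi = float(latent["midpoint"][idx])
        else:
            ph = am = mi = float("nan")
        return TouchEvent(
            onset=float(t[idx]),
            direction=direction,
            angle_at_touch=float(clipped[idx]),
            phase_at_touch=ph,
            amplitude_at_touch=am,
            midpoint_at_touch=mi,
            curvature_pre=float(curvature[pre_idx]),
            radial_distance=radial,
        )

    in_contact = False
    for i in range(n):
        if above[i] and not in_contact:
            in_contact = True
            # upward crossing while in reach = protraction onset; a contact
            # that opens because the pole rose under an already-protracted
            # whisker has no protraction onset
            if i > 0 and available[i - 1] and not above[i - 1]:
                events.append(snapshot(i, PROTRACTION))
        elif in_contact and not above[i]:
            in_contact = False
            if available[i]:
                events.append(snapshot(i, RETRACTION))

    return TouchResult(events=events, clipped_angle=clipped, follicle=follicle,
                       curvature=curvature, pole_angle=theta_pole)


# ---------------------------------------------------------------------------
# choice
# ---------------------------------------------------------------------------

def _sigmoid(z: float) -> float:
    if z >= 0:
        return 1.0 / (1.0 + math.exp(-z))
    ez = math.exp(z)
    return ez / (1.0 + ez)


def choice_probability(
    kinematic_value: float,
    touch_count: int,
    config: SessionConfig,
) -> float:
    """Lick probability under the generative logistic rule.

    The rule operates on reference-normalized features: the configured
    kinematic feature (midpoint-at-touch by default, angle-at-touch as an
    option) and the pre-decision touch count. Zero-touch trials use the
    normalized-midpoint placeholder 0 (the reference mean), so they are
    decided by the count term and bias alone.
    """
    w_kin, w_count, bias = config.choice_weights
    ref = (config.choice_midpoint_ref if config.choice_feature == "midpoint"
           else config.choice_angle_ref)
    if touch_count == 0 or not np.isfinite(kinematic_value):
        x_kin = 0.0
    else:
        x_kin = (kinematic_value - ref[0]) / ref[1]
    x_count = (touch_count - config.choice_count_ref[0]) / config.choice_count_ref[1]
    return _sigmoid(w_kin * x_kin + w_count * x_count + bias)


def generate_choice(
    kinematic_value: float,
    touch_count: int,
    config: SessionConfig,
    rng: np.random.Generator,
) -> Tuple[str, float]:
    """Draw a Bernoulli choice from the generative rule; returns (choice, p)."""
    p = choice_probability(kinematic_value, touch_count, config)
    return (LICK if rng.random() < p else NO_LICK), p


# ---------------------------------------------------------------------------
# trials and sessions
# ---------------------------------------------------------------------------

def _position_ranges(config: SessionConfig):
    if config.task_variant == "anteroposterior":
        return config.go_range, config.nogo_range
    if config.task_variant == "angle":

        def angle_of(p):
            return math.degrees(math.atan2(p, config.lateral_offset))

        return ((angle_of(config.go_range[0]), angle_of(config.go_range[1])),
                (angle_of(config.nogo_range[0]), angle_of(config.nogo_range[1])))
    return config.distance_go_range, config.distance_nogo_range


def generate_trial(
    config: SessionConfig,
    trial_id: int,
    pole_position: float,
    trial_type: str,
    rng: np.random.Generator,
) -> Trial:
    """Generate one trial end to end: trace, touches, choice, licks, outcome."""
    theta_pole_rest = pole_angle_at_rest(pole_position, config)
    angle, latent = generate_whisking_trace(config, rng, pole_angle=theta_pole_rest)
    follicle0 = follicle_from_angle(angle, config)
    touch = generate_touches(angle, follicle0, pole_position, config,
                             latent=latent, rng=rng)

    answer_start, answer_end = config.answer_window
    pre_answer = [e for e in touch.events if e.onset < answer_start]
    count = len(pre_answer)
    if count:
        kin_value = float(np.mean([
            e.midpoint_at_touch if config.choice_feature == "midpoint"
            else e.angle_at_touch
            for e in pre_answer
        ]))
    else:
        kin_value = float("nan")
    choice, p_lick = generate_choice(kin_value, count, config, rng)

    licks: List[float] = []
    if choice == LICK:
        delay = rng.gamma(config.lick_delay_shape, config.lick_delay_scale)
        decision = min(answer_start + delay, answer_end - 50.0)
        if rng.random() < config.early_lick_prob:
            licks.append(float(rng.uniform(answer_start - 300.0, answer_start - 10.0)))
        tlick = decision
        while tlick < answer_end + 300.0 and tlick < config.trial_duration:
            licks.append(float(tlick))
            tlick += config.lick_interval * (1.0 + 0.1 * rng.standard_normal())
    elif rng.random() < 0.05:
        # occasional stray lick outside the answer period (ignored downstream)
        licks.append(float(rng.uniform(answer_start - 300.0, answer_start - 10.0)))

    latent["lick_probability"] = p_lick
    latent["choice_features"] = np.array([kin_value, float(count)])

    return Trial(
        trial_id=trial_id,
        pole_position=pole_position,
        trial_type=trial_type,
        angle_series=touch.clipped_angle,
        curvature_series=touch.curvature,
        follicle_series=touch.follicle,
        touch_events=touch.events,
        lick_times=licks,
        choice=choice,
        outcome=outcome_of(trial_type, choice),
        latent=latent,
    )


def generate_session(config: SessionConfig) -> Session:
    """Generate a full session: 50/50 go/no-go trials, positions uniform
    within their range, all randomness derived from the session seed."""
    root = config.seed_sequence()
    session_ss, *trial_ss = root.spawn(config.n_trials + 1)
    session_rng = np.random.default_rng(session_ss)

    n_go = config.n_trials // 2
    types = np.array([GO] * n_go + [NOGO] * (config.n_trials - n_go))
    session_rng.shuffle(types)
    go_rng, nogo_rng = _position_ranges(config)

    trials = []
    for i, (tt, ss) in enumerate(zip(types, trial_ss)):
        rng = np.random.default_rng(ss)
        lo, hi = go_rng if tt == GO else nogo_rng
        position = float(rng.uniform(lo, hi))
        trials.append(generate_trial(config, i, position, str(tt), rng))
    return Session(config=config, trials=trials)
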