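"""Per-trial predictor extraction with pre-decision windowing.

Each trial is reduced to the 13 predictors used by the decision classifiers:
motor position, touch presence, touch count, roll angle (mean curvature 1 ms
before touch), whisk latency (mean time from the nearest preceding whisking
trough to touch), cue latency (cue onset to first touch), radial distance,
and the angle / phase / amplitude / midpoint of the whisker averaged over
touches; "combined" and "hilbert" are named subsets of these. All touch-
conditioned quantities are computed over pre-decision touches only — the
decision point is the first lick of the answer period, with the session
median substituted on no-lick trials — and touchless trials carry NaN
missing markers rather than imputed zeros.

Retraction touches flip the phase convention by ~pi, so for the Hilbert
decoders the phase/amplitude/midpoint means are recomputed over protraction
touches only and trials with exclusively retraction touches are excluded
(:func:`apply_retraction_exclusion`).
"""

from __future__ import annotations

import warnings
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import SessionConfig
from .kinematics import KinematicDecomposition, Whisk, hilbert_decompose, segment_whisks
from .session import LICK, PROTRACTION, Session, Trial

HILBERT_FEATURES = ("phase", "amplitude", "midpoint")

FEATURE_COLUMNS = [
    "trial_id", "motor_position", "touch_presence", "touch_count", "roll_angle",
    "whisk_latency", "cue_latency", "radial_distance", "angle", "phase",
    "amplitude", "midpoint",
    "protraction_phase", "protraction_amplitude", "protraction_midpoint",
    "protraction_touch_flag", "trial_type", "choice", "decision_lick_ms",
]

#: named predictor subsets used throughout the analysis
FEATURE_SETS = {
    "touch_presence": ["touch_presence"],
    "touch_count": ["touch_count"],
    "roll_angle": ["roll_angle"],
    "whisk_latency": ["whisk_latency"],
    "cue_latency": ["cue_latency"],
    "radial_distance": ["radial_distance"],
    "angle": ["angle"],
    "motor_position": ["motor_position"],
    "combined": ["roll_angle", "cue_latency", "whisk_latency", "touch_count",
                 "radial_distance", "angle"],
    "hilbert": ["protraction_phase", "protraction_amplitude", "protraction_midpoint"],
    "phase": ["protraction_phase"],
    "amplitude": ["protraction_amplitude"],
    "midpoint": ["protraction_midpoint"],
    "midpoint+count": ["protraction_midpoint", "touch_count"],
    "angle+count": ["angle", "touch_count"],
    "amplitude+count": ["protraction_amplitude", "touch_count"],
    "phase+count": ["protraction_phase", "touch_count"],
}


def answer_period_licks(trial: Trial, config: SessionConfig) -> List[float]:
    """Licks at or after the answer-period start (earlier licks are ignored)."""
    start, _ = config.answer_window
    return [t for t in trial.lick_times if t >= start]


def decision_lick_time(trial: Trial, session: Session) -> float:
    """Decision point of a trial, ms from trial start.

    For lick trials: the first lick with time >= answer-period start (closed
    left endpoint). For no-lick trials: the session median of the lick
    trials' decision times. A session with zero lick trials has no defined
    median and raises ``ValueError``.
    """
    licks = answer_period_licks(trial, session.config)
    if licks:
        return float(min(licks))
    medians = [min(lk) for t in session.trials
               if (lk := answer_period_licks(t, session.config))]
    if not medians:
        raise ValueError("session has no lick trials: median decision time undefined")
    return float(np.median(medians))


def decision_times(session: Session) -> np.ndarray:
    """Per-trial decision times for a whole session (vectorized median rule)."""
    firsts = [answer_period_licks(t, session.config) for t in session.trials]
    lick_firsts = [min(lk) for lk in firsts if lk]
    if not lick_firsts:
        raise ValueError("session has no lick trials: median decision time undefined")
    median = float(np.median(lick_firsts))
    return np.array([min(lk) if lk else median for lk in firsts])


def filter_predecision(trial: Trial, decision_time: float) -> Trial:
    """A view of the trial containing only touches strictly before the
    decision time (a touch at exactly the decision time is excluded).
    Time-series arrays are shared, not copied."""
    kept = [e for e in trial.touch_events if e.onset < decision_time]
    return Trial(
        trial_id=trial.trial_id,
        pole_position=trial.pole_position,
        trial_type=trial.trial_type,
        angle_series=trial.angle_series,
        curvature_series=trial.curvature_series,
        follicle_series=trial.follicle_series,
        touch_events=kept,
        lick_times=trial.lick_times,
        choice=trial.choice,
        outcome=trial.outcome,
        latent=trial.latent,
    )


def _mean_or_nan(values: Sequence[float]) -> float:
    return float(np.mean(values)) if len(values) else float("nan")


def extract_features(
    trial: Trial,
    decomposition: KinematicDecomposition,
    whisks: Sequence[Whisk],
    decision_time: float,
    cue_time: Optional[float] = None,
    config: Optional[SessionConfig] = None,
) -> dict:
    """One trial's feature row.

    Kinematic snapshots (angle, phase, amplitude, midpoint) are sampled from
    the decomposition at each pre-decision touch onset; roll angle is the
    curvature one sample before onset; whisk latency measures each touch
    against the nearest preceding whisking trough (phase-wrap troughs of the
    decomposition). Touch-conditioned features of touchless trials are NaN.
    """
    if cue_time is None:
        if config is None:
            raise ValueError("either cue_time or config must be given")
        cue_time = config.pole_trigger_time
    view = filter_predecision(trial, decision_time)
    touches = view.touch_events
    fs = decomposition.sample_rate

    trough_times = decomposition.trough_times()
    angle_v, phase_v, amp_v, mid_v, curv_v, rad_v, lat_v = [], [], [], [], [], [], []
    prot = {"phase": [], "amplitude": [], "midpoint": []}
    for e in touches:
        idx = decomposition.index_at(e.onset)
        pre_idx = max(idx - int(round(fs / 1000.0)), 0)  # 1 ms before onset
        angle_v.append(float(decomposition.angle[idx]))
        phase_v.append(float(decomposition.phase[idx]))
        amp_v.append(float(decomposition.amplitude[idx]))
        mid_v.append(float(decomposition.midpoint[idx]))
        curv_v.append(float(trial.curvature_series[pre_idx]))
        rad_v.append(e.radial_distance)
        if e.direction == PROTRACTION:
            prot["phase"].append(float(decomposition.phase[idx]))
            prot["amplitude"].append(float(decomposition.amplitude[idx]))
            prot["midpoint"].append(float(decomposition.midpoint[idx]))
        earlier = trough_times[trough_times <= e.onset]
        if earlier.size:
            lat_v.append(e.onset - float(earlier[-1]))
        else:
            warnings.warn(
                f"touch at {e.onset:.0f} ms has no preceding whisking trough; "
                "excluded from whisk latency")

    n_touch = len(touches)
    first_touch = touches[0].onset if n_touch else float("nan")
    has_protraction = len(prot["midpoint"]) > 0
    return {
        "trial_id": trial.trial_id,
        "motor_position": trial.pole_position,
        "touch_presence": 1.0 if n_touch else 0.0,
        "touch_count": float(n_touch),
        "roll_angle": _mean_or_nan(curv_v),
        "whisk_latency": _mean_or_nan(lat_v),
        "cue_latency": first_touch - cue_time if n_touch else float("nan"),
        "radial_distance": _mean_or_nan(rad_v),
        "angle": _mean_or_nan(angle_v),
        "phase": _mean_or_nan(phase_v),
        "amplitude": _mean_or_nan(amp_v),
        "midpoint": _mean_or_nan(mid_v),
        "protraction_phase": _mean_or_nan(prot["phase"]),
        "protraction_amplitude": _mean_or_nan(prot["amplitude"]),
        "protraction_midpoint": _mean_or_nan(prot["midpoint"]),
        "protraction_touch_flag": 1.0 if has_protraction else 0.0,
        "trial_type": trial.trial_type,
        "choice": trial.choice,
        "decision_lick_ms": decision_time,
    }


def build_feature_table(
    session: Session,
    decompositions: Optional[Sequence[KinematicDecomposition]] = None,
    whisks: Optional[Sequence[Sequence[Whisk]]] = None,
) -> pd.DataFrame:
    """Feature rows for every trial of a session, one DataFrame.

    Decompositions and whisk segmentations are computed on demand when not
    supplied (e.g. when they were already exported to the session file).
    """
    config = session.config
    dts = decision_times(session)
    rows = []
    for i, trial in enumerate(session.trials):
        if decompositions is not None:
            dec = decompositions[i]
        else:
            dec = hilbert_decompose(trial.angle_series, config.sample_rate)
        wk = whisks[i] if whisks is not None else segment_whisks(
            dec, nominal_freq=config.whisking_freq)
        rows.append(extract_features(trial, dec, wk, float(dts[i]),
                                     cue_time=config.pole_trigger_time))
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def apply_retraction_exclusion(
    feature_table: pd.DataFrame,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict a feature table to the rows eligible for the Hilbert decoders.

    Returns ``(hilbert_table, excluded)``: the eligible subtable has its
    phase/amplitude/midpoint columns replaced by the protraction-only means;
    trials whose pre-decision touches were exclusively retractions (and,
    vacuously, touchless trials) land in ``excluded``. Non-Hilbert features,
    including touch count, are untouched.
    """
    eligible = feature_table["protraction_touch_flag"] == 1.0
    hil = feature_table.loc[eligible].copy()
    for name in HILBERT_FEATURES:
        hil[name] = hil[f"protraction_{name}"]
    excluded = feature_table.loc[~eligible & (feature_table["touch_count"] > 0)]
    return hil, excluded


def mean_normalize(values: Iterable[float]) -> np.ndarray:
    """Mean normalization x' = (x - mean(x)) / (max(x) - min(x)).

    The output has mean 0 and peak-to-peak range exactly 1. A constant input
    has zero range and raises ``ValueError``.
    """
    x = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                   dtype=float)
    rng = float(np.max(x) - np.min(x))
    if rng == 0.0:
        raise ValueError("cannot mean-normalize a constant series (zero range)")
    return (x - x.mean()) / rng
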