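"""Session containers and on-disk format.

A :class:`Session` is an ordered collection of :class:`Trial` objects plus the
:class:`~whiskloc.config.SessionConfig` that produced (or described) them.
Each trial carries the whisker azimuthal-angle time series (degrees, 1 kHz by
default), a curvature trace (1/mm), the 2-D follicle trajectory (mm), touch
events, lick times, the animal's choice, and the outcome.

On disk a session is one HDF5 container (all per-trial arrays and events,
written deterministically) plus a human-inspectable ``trials.csv`` sidecar.
The HDF5 schema is versioned; reading a container with a different major
schema version fails loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import h5py
import numpy as np
import pandas as pd

from .config import SessionConfig

SCHEMA_VERSION = "1.0"

GO, NOGO = "go", "nogo"
LICK, NO_LICK = "lick", "no_lick"
PROTRACTION, RETRACTION = "protraction", "retraction"

#: columns of the trial table sidecar, in bit-stable order
TRIAL_TABLE_COLUMNS = [
    "trial_id",
    "trial_type",
    "pole_position_mm",
    "choice",
    "outcome",
    "n_touches",
    "decision_lick_ms",
]


def outcome_of(trial_type: str, choice: str) -> str:
    """Deterministic outcome table: go+lick=hit, go+no-lick=miss,
    nogo+lick=false_alarm, nogo+no-lick=correct_rejection."""
    if trial_type == GO:
        return "hit" if choice == LICK else "miss"
    return "false_alarm" if choice == LICK else "correct_rejection"


@dataclass
class TouchEvent:
    """A whisker-pole contact event with a kinematic snapshot at onset.

    ``curvature_pre`` is sampled exactly one sample before onset (1 ms at
    1 kHz). The angle/phase/amplitude/midpoint snapshots stored by the
    generator are ground-truth latents; the analysis pipeline re-derives its
    own from the Hilbert decomposition.
    """

    onset: float                  # ms
    direction: str                # protraction | retraction
    angle_at_touch: float         # degrees
    phase_at_touch: float         # radians
    amplitude_at_touch: float     # degrees
    midpoint_at_touch: float      # degrees
    curvature_pre: float          # 1/mm
    radial_distance: float        # mm, follicle -> pole at onset

    def to_row(self) -> list:
        return [
            self.onset,
            1.0 if self.direction == PROTRACTION else 0.0,
            self.angle_at_touch,
            self.phase_at_touch,
            self.amplitude_at_touch,
            self.midpoint_at_touch,
            self.curvature_pre,
            self.radial_distance,
        ]

    @classmethod
    def from_row(cls, row) -> "TouchEvent":
        return cls(
            onset=float(row[0]),
            direction=PROTRACTION if row[1] > 0.5 else RETRACTION,
            angle_at_touch=float(row[2]),
            phase_at_touch=float(row[3]),
            amplitude_at_touch=float(row[4]),
            midpoint_at_touch=float(row[5]),
            curvature_pre=float(row[6]),
            radial_distance=float(row[7]),
        )


@dataclass
class Trial:
    trial_id: int
    pole_position: float          # mm along AP axis (deg / mm for task variants)
    trial_type: str               # go | nogo
    angle_series: np.ndarray      # degrees
    curvature_series: np.ndarray  # 1/mm
    follicle_series: np.ndarray   # (n, 2) mm
    touch_events: List[TouchEvent] = field(default_factory=list)
    lick_times: List[float] = field(default_factory=list)
    choice: str = NO_LICK
    outcome: str = ""
    #: latent ground truth from the generator (None for real data)
    latent: Optional[dict] = None

    def __post_init__(self) -> None:
        if not self.outcome:
            self.outcome = outcome_of(self.trial_type, self.choice)

    @property
    def n_touches(self) -> int:
        return len(self.touch_events)


@dataclass
class Session:
    config: SessionConfig
    trials: List[Trial]

    def __len__(self) -> int:
        return len(self.trials)

    def trial_table(self, decision_times: Optional[np.ndarray] = None) -> pd.DataFrame:
        """Per-trial summary table in the canonical column order."""
        rows = []
        for i, t in enumerate(self.trials):
            dl = np.nan if decision_times is None else decision_times[i]
            rows.append(
                [t.trial_id, t.trial_type, t.pole_position, t.choice, t.outcome,
                 t.n_touches, dl]
            )
        return pd.DataFrame(rows, columns=TRIAL_TABLE_COLUMNS)


LATENT_KEYS = ("midpoint", "amplitude", "phase", "cue_time", "whisk_peak_times",
               "whisk_peak_targets", "whisk_trough_times", "first_touch_whisk",
               "lick_probability", "choice_features")


def write_session(session: Session, path, trials_csv: Optional[str] = None) -> None:
    """Write a session to an HDF5 container (deterministic bytes for a fixed
    session) and optionally a CSV trial-table sidecar."""
    with h5py.File(path, "w", track_order=False) as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        cfg = f.create_group("config")
        for key, value in session.config.to_dict().items():
            if isinstance(value, list):
                cfg.attrs[key] = np.asarray(value, dtype=float)
            else:
                cfg.attrs[key] = value
        trials = f.create_group("trials")
        for t in session.trials:
            g = trials.create_group(f"{t.trial_id:05d}")
            g.attrs["trial_id"] = t.trial_id
            g.attrs["pole_position"] = t.pole_position
            g.attrs["trial_type"] = t.trial_type
            g.attrs["choice"] = t.choice
            g.attrs["outcome"] = t.outcome
            for name, arr in (
                ("angle", t.angle_series),
                ("curvature", t.curvature_series),
                ("follicle", t.follicle_series),
            ):
                g.create_dataset(name, data=np.asarray(arr, dtype=np.float64),
                                 track_times=False)
            touch = np.asarray([e.to_row() for e in t.touch_events],
                               dtype=np.float64).reshape(-1, 8)
            g.create_dataset("touches", data=touch, track_times=False)
            g.create_dataset("licks", data=np.asarray(t.lick_times, dtype=np.float64),
                             track_times=False)
            if t.latent is not None:
                lat = g.create_group("latent")
                for key, value in t.latent.items():
                    value = np.asarray(value, dtype=np.float64)
                    lat.create_dataset(key, data=value, track_times=False)
    if trials_csv is not None:
        session.trial_table().to_csv(trials_csv, index=False)


def read_session(path) -> Session:
    with h5py.File(path, "r") as f:
        version = str(f.attrs.get("schema_version", ""))
        if version.split(".")[0] != SCHEMA_VERSION.split(".")[0]:
            raise IOError(
                f"session schema version {version!r} is incompatible with "
                f"reader version {SCHEMA_VERSION!r}"
            )
        cfg = {}
        for key, value in f["config"].attrs.items():
            if isinstance(value, np.ndarray):
                cfg[key] = tuple(value.tolist())
            elif isinstance(value, (np.integer,)):
                cfg[key] = int(value)
            elif isinstance(value, (np.floating,)):
                cfg[key] = float(value)
            else:
                cfg[key] = str(value)
        # integer-typed fields round-trip through HDF5 attrs
        cfg["n_trials"] = int(cfg["n_trials"])
        cfg["rng_seed"] = int(cfg["rng_seed"])
        config = SessionConfig.from_dict(cfg)
        trials = []
        for name in sorted(f["trials"]):
            g = f["trials"][name]
            latent = None
            if "latent" in g:
                latent = {k: np.asarray(g["latent"][k]) for k in g["latent"]}
                for key in ("cue_time", "first_touch_whisk", "lick_probability"):
                    if key in latent and latent[key].ndim == 0:
                        latent[key] = float(latent[key])
            trials.append(
                Trial(
                    trial_id=int(g.attrs["trial_id"]),
                    pole_position=float(g.attrs["pole_position"]),
                    trial_type=str(g.attrs["trial_type"]),
                    angle_series=np.asarray(g["angle"]),
                    curvature_series=np.asarray(g["curvature"]),
                    follicle_series=np.asarray(g["follicle"]),
                    touch_events=[TouchEvent.from_row(r) for r in np.asarray(g["touches"])],
                    lick_times=list(np.asarray(g["licks"])),
                    choice=str(g.attrs["choice"]),
                    outcome=str(g.attrs["outcome"]),
                    latent=latent,
                )
            )
    return Session(config=config, trials=trials)


def sessions_equal(a: Session, b: Session, check_latent: bool = True) -> bool:
    """Structural equality of two sessions (arrays compared exactly)."""
    if a.config.to_dict() != b.config.to_dict() or len(a) != len(b):
        return False
    for ta, tb in zip(a.trials, b.trials):
        if (ta.trial_id, ta.trial_type, ta.choice, ta.outcome) != (
                tb.trial_id, tb.trial_type, tb.choice, tb.outcome):
            return False
        if ta.pole_position != tb.pole_position:
            return False
        for xa, xb in ((ta.angle_series, tb.angle_series),
                       (ta.curvature_series, tb.curvature_series),
                       (ta.follicle_series, tb.follicle_series)):
            if not np.array_equal(xa, xb):
                return False
        if ta.lick_times != tb.lick_times or len(ta.touch_events) != len(tb.touch_events):
            return False
        for ea, eb in zip(ta.touch_events, tb.touch_events):
            if ea.to_row() != eb.to_row():
                return False
        if check_latent:
            la, lb = ta.latent or {}, tb.latent or {}
            if set(la) != set(lb):
                return False
            for key in la:
                if not np.array_equal(np.asarray(la[key], dtype=float),
                                      np.asarray(lb[key], dtype=float),
                                      equal_nan=True):
                    return False
    return True
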