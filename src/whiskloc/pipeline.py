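"""End-to-end orchestration: simulate -> decompose -> features -> classify ->
behavior, as a configured, logged, reproducible run.

A :class:`RunConfig` names the feature subsets to evaluate; every stage's
outputs land in a run directory and are listed, with content hashes and the
seeds used, in ``manifest.json``. Rerunning the same config reproduces
identical hashes for the deterministic artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import (boundary_discrimination, lick_probability_by_touch_count,
                       session_psychometric, whisk_count_distributions)
from .classifier import cross_validate, fit_two_stage, labels_from
from .config import ConfigurationError, SessionConfig
from .features import FEATURE_SETS, build_feature_table, decision_times
from .kinematics import hilbert_decompose, segment_whisks
from .session import Session, write_session
from .synth import generate_session

log = logging.getLogger("whiskloc")

DEFAULT_CHOICE_MODELS = [
    "touch_count", "roll_angle", "whisk_latency", "cue_latency",
    "radial_distance", "angle", "combined", "hilbert",
    "phase", "amplitude", "midpoint",
]
DEFAULT_TRIAL_TYPE_MODELS = ["touch_presence", "touch_count", "angle"]
DEFAULT_TWO_STAGE = ["protraction_midpoint", "angle",
                     "protraction_amplitude", "protraction_phase"]


@dataclass
class RunConfig:
    session: SessionConfig = field(default_factory=SessionConfig)
    choice_models: List[str] = field(default_factory=lambda: list(DEFAULT_CHOICE_MODELS))
    trial_type_models: List[str] = field(
        default_factory=lambda: list(DEFAULT_TRIAL_TYPE_MODELS))
    two_stage_features: List[str] = field(default_factory=lambda: list(DEFAULT_TWO_STAGE))
    cv_iterations: int = 20
    cv_folds: int = 5
    cv_seed: int = 7
    out_dir: str = "run"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        known_predictors = set(FEATURE_SETS["combined"]) | set(
            sum(FEATURE_SETS.values(), []))
        for name in list(self.choice_models) + list(self.trial_type_models):
            if name not in FEATURE_SETS:
                raise ConfigurationError(f"undefined feature set: {name!r}")
        for feat in self.two_stage_features:
            if feat not in known_predictors:
                raise ConfigurationError(f"undefined predictor: {feat!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        session = SessionConfig.from_dict(raw.pop("session", {}))
        return cls(session=session, **raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_full_analysis(run_config: RunConfig) -> dict:
    """Execute all stages and return the run manifest.

    The manifest lists every output file with its content hash, the seeds
    and config, and per-stage wall times (logged for auditability only).
    Any stage failure aborts with the stage name in the raised error.
    """
    run_config.validate()
    out = Path(run_config.out_dir)
    (out / "fits").mkdir(parents=True, exist_ok=True)
    (out / "report").mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "session_seed": run_config.session.rng_seed,
        "cv_seed": run_config.cv_seed,
        "config": {"session": run_config.session.to_dict(),
                   "choice_models": run_config.choice_models,
                   "trial_type_models": run_config.trial_type_models,
                   "two_stage_features": run_config.two_stage_features,
                   "cv_iterations": run_config.cv_iterations,
                   "cv_folds": run_config.cv_folds},
        "stages": {},
        "files": {},
    }
    timings: Dict[str, float] = {}

    def stage(name):
        class _Stage:
            def __enter__(self_inner):
                log.info("stage %s: start", name)
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                timings[name] = time.perf_counter() - self_inner.t0
                if exc is not None:
                    raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
                log.info("stage %s: done in %.2fs", name, timings[name])
        return _Stage()

    with stage("simulate"):
        session = generate_session(run_config.session)
        write_session(session, out / "session.h5", trials_csv=out / "trials.csv")

    with stage("decompose"):
        cfg = run_config.session
        decomps = [hilbert_decompose(t.angle_series, cfg.sample_rate)
                   for t in session.trials]
        whisks = [segment_whisks(d, nominal_freq=cfg.whisking_freq)
                  for d in decomps]

    with stage("features"):
        table = build_feature_table(session, decomps, whisks)
        table.to_csv(out / "features.csv", index=False)

    cv_kwargs = dict(iterations=run_config.cv_iterations, folds=run_config.cv_folds)
    rng = np.random.default_rng(run_config.cv_seed)

    with stage("classify"):
        fits = {}
        for target, names in (("choice", run_config.choice_models),
                              ("trial_type", run_config.trial_type_models)):
            for name in names:
                predictors = FEATURE_SETS[name]
                sub = table.dropna(subset=predictors)
                res = cross_validate(sub, predictors, target,
                                     rng=np.random.default_rng(
                                         int(rng.integers(2 ** 31))),
                                     **cv_kwargs)
                key = f"{target}__{name}"
                res.to_json(out / "fits" / f"{key}.json")
                fits[key] = res
        for feat in run_config.two_stage_features:
            count_fit, touch_fit, pred = fit_two_stage(
                table, feat, "choice",
                rng=np.random.default_rng(int(rng.integers(2 ** 31))), **cv_kwargs)
            key = f"choice__two_stage_{feat}"
            payload = touch_fit.to_dict()
            y = labels_from(table, "choice")
            payload["two_stage_accuracy"] = float(np.mean(pred == y))
            with open(out / "fits" / f"{key}.json", "w") as fh:
                json.dump(payload, fh, indent=1, sort_keys=True)
            fits[key] = touch_fit

    with stage("behavior"):
        dts = decision_times(session)
        curve = session_psychometric(session)
        pd.DataFrame({
            "bin_left": curve.bin_edges[:-1],
            "bin_right": curve.bin_edges[1:],
            "lick_probability": curve.lick_probability,
            "n_trials": curve.trial_counts,
            "ci_low": curve.ci_low,
            "ci_high": curve.ci_high,
        }).to_csv(out / "report" / "psychometric.csv", index=False)
        boundary_discrimination(session).to_csv(
            out / "report" / "boundary_discrimination.csv", index=False)
        lick_probability_by_touch_count(session).to_csv(
            out / "report" / "lick_by_touch_count.csv", index=False)
        wc = whisk_count_distributions(session, whisks, dts)
        with open(out / "report" / "whisk_kl.json", "w") as fh:
            json.dump({"kl_pre": wc.kl_pre, "kl_post": wc.kl_post,
                       "median_first_touch_ms": wc.median_first_touch},
                      fh, indent=1, sort_keys=True)

    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["files"][str(path.relative_to(out))] = _sha256(path)
    manifest["stages"] = {k: round(v, 3) for k, v in timings.items()}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def compare_models(run_dir) -> pd.DataFrame:
    """Ranked model table from a run directory's fits.

    Rows are sorted by mean held-out MCC (stable sort, so duplicate models
    keep their relative order); SEM is across CV folds. Requires at least
    two fitted models.
    """
    run_dir = Path(run_dir)
    rows = []
    for path in sorted((run_dir / "fits").glob("*.json")):
        with open(path) as fh:
            d = json.load(fh)
        rows.append([path.stem, d["target_label"],
                     ",".join(d["predictor_names"]), d["mean_mcc"],
                     d["sem_mcc"], d["mean_accuracy"], d["chosen_lambda"]])
    if len(rows) < 2:
        raise ValueError("need at least two fitted models to compare")
    df = pd.DataFrame(rows, columns=["model", "target", "predictors", "mean_mcc",
                                     "sem_mcc", "mean_accuracy", "chosen_lambda"])
    return df.sort_values("mean_mcc", ascending=False,
                          kind="stable").reset_index(drop=True)
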