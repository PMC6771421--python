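"""Session-level behavioral statistics.

Psychometric curves (lick probability by binned pole position), boundary
discrimination (lick-probability difference between go/no-go windows of
increasing width around the boundary, with a closed-form two-sample t on the
Bernoulli lick indicators), adaptive-whisking count distributions before and
after the first touch with their KL divergence, touch-count-conditioned lick
probabilities, protraction targeting by whisk index, and the deviation score
comparing classifier psychometric curves to the subject's.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .config import SessionConfig
from .kinematics import Whisk, hilbert_decompose, kl_divergence, segment_whisks
from .session import GO, LICK, NOGO, Session
from .features import decision_times
from .synth import boundary_angle

DEFAULT_MAX_DISTANCES = (0.5, 1.0, 2.0, 3.0, 4.0, 5.0)


@dataclass
class PsychometricCurve:
    """Lick probability per position bin with binomial confidence intervals."""

    bin_edges: np.ndarray
    lick_probability: np.ndarray   # NaN for empty bins
    trial_counts: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    target: str = "subject"

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def _binomial_ci(k: np.ndarray, n: np.ndarray, alpha: float = 0.05):
    """Clopper-Pearson interval; always contains the point estimate."""
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        low = np.where(k > 0, sstats.beta.ppf(alpha / 2, k, n - k + 1), 0.0)
        high = np.where(k < n, sstats.beta.ppf(1 - alpha / 2, k + 1, n - k), 1.0)
    low = np.where(n > 0, low, np.nan)
    high = np.where(n > 0, high, np.nan)
    return low, high


def psychometric_curve(
    positions: Sequence[float],
    licks: Sequence[int],
    bin_width: float = 1.0,
    position_range: Optional[Tuple[float, float]] = None,
    target: str = "subject",
) -> PsychometricCurve:
    """Per-bin lick probability over pole position.

    Bins are aligned to ``position_range`` (defaults to the data's span) so
    that with the default 1 mm width over the 10 mm task range the go/no-go
    boundary falls on a bin edge. ``licks`` may be the subject's choices or
    a classifier's predictions. Empty bins are NaN.
    """
    positions = np.asarray(positions, dtype=float)
    licks = np.asarray(licks, dtype=float)
    if positions.size == 0:
        raise ValueError("no trials to bin")
    if position_range is None:
        position_range = (float(positions.min()), float(positions.max()))
    lo, hi = position_range
    n_bins = max(int(np.ceil((hi - lo) / bin_width - 1e-9)), 1)
    edges = lo + bin_width * np.arange(n_bins + 1)
    idx = np.clip(np.searchsorted(edges, positions, side="right") - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    hits = np.bincount(idx, weights=licks, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        prob = np.where(counts > 0, hits / counts, np.nan)
    ci_low, ci_high = _binomial_ci(hits, counts)
    return PsychometricCurve(bin_edges=edges, lick_probability=prob,
                             trial_counts=counts, ci_low=ci_low, ci_high=ci_high,
                             target=target)


def session_psychometric(session: Session, bin_width: float = 1.0,
                         predictions: Optional[Sequence[int]] = None,
                         target: str = "subject") -> PsychometricCurve:
    """Psychometric curve of a session, for the subject's choices or for a
    classifier's predictions aligned to trial order."""
    cfg = session.config
    positions = [t.pole_position for t in session.trials]
    if predictions is None:
        licks = [1 if t.choice == LICK else 0 for t in session.trials]
    else:
        licks = list(predictions)
    if cfg.task_variant == "anteroposterior":
        rng = (cfg.go_range[0], cfg.nogo_range[1])
    elif cfg.task_variant == "distance":
        rng = (cfg.distance_go_range[0], cfg.distance_nogo_range[1])
    else:
        rng = None
    return psychometric_curve(positions, licks, bin_width=bin_width,
                              position_range=rng, target=target)


def _welch_t(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sample t statistic (pooled variance) on Bernoulli indicators,
    computed from its closed form."""
    n1, n2 = x.size, y.size
    v1 = x.var(ddof=1) if n1 > 1 else 0.0
    v2 = y.var(ddof=1) if n2 > 1 else 0.0
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / max(n1 + n2 - 2, 1)
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    if se == 0:
        return 0.0 if x.mean() == y.mean() else np.inf * np.sign(x.mean() - y.mean())
    return float((x.mean() - y.mean()) / se)


def boundary_discrimination(
    session: Session,
    max_distances: Sequence[float] = DEFAULT_MAX_DISTANCES,
    predictions: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Lick-probability difference between go and no-go windows around the
    discrimination boundary.

    For each max distance d the go window is [boundary - d, boundary) and
    the no-go window [boundary, boundary + d] (cumulative windows). Returns
    a row per distance with the probability difference (go - nogo), a
    two-sample t statistic on the per-trial lick indicators, and the trial
    counts; a distance with an unoccupied side is marked missing (NaN).
    """
    cfg = session.config
    boundary = cfg.boundary_position
    positions = np.array([t.pole_position for t in session.trials])
    if predictions is None:
        licks = np.array([1.0 if t.choice == LICK else 0.0 for t in session.trials])
    else:
        licks = np.asarray(predictions, dtype=float)
    rows = []
    for d in max_distances:
        go_side = (positions >= boundary - d) & (positions < boundary)
        nogo_side = (positions >= boundary) & (positions <= boundary + d)
        if not go_side.any() or not nogo_side.any():
            rows.append([d, np.nan, np.nan, int(go_side.sum()), int(nogo_side.sum())])
            continue
        x, y = licks[go_side], licks[nogo_side]
        rows.append([d, float(x.mean() - y.mean()), _welch_t(x, y),
                     int(go_side.sum()), int(nogo_side.sum())])
    return pd.DataFrame(rows, columns=["max_distance", "lick_diff", "t_stat",
                                       "n_go", "n_nogo"])


@dataclass
class WhiskCountResult:
    pre_counts_touch: np.ndarray
    pre_counts_notouch: np.ndarray
    post_counts_touch: np.ndarray
    post_counts_notouch: np.ndarray
    kl_pre: float
    kl_post: float
    median_first_touch: float


def _count_hist(counts: np.ndarray, n_bins: int) -> np.ndarray:
    return np.bincount(np.clip(counts.astype(int), 0, n_bins - 1), minlength=n_bins)


def whisk_count_distributions(
    session: Session,
    whisks_per_trial: Optional[Sequence[Sequence[Whisk]]] = None,
    decision: Optional[np.ndarray] = None,
) -> WhiskCountResult:
    """Whisk counts in the pre- and post-first-touch windows, split by touch
    and no-touch trials, with the KL divergence between the two groups'
    count distributions in each window.

    The pre window runs from stimulus (pole) onset to the first touch, the
    post window from first touch to the decision lick; no-touch trials use
    the session median first-touch time. A session without touch trials has
    no median and raises ``ValueError``.
    """
    cfg = session.config
    if whisks_per_trial is None:
        whisks_per_trial = [
            segment_whisks(hilbert_decompose(t.angle_series, cfg.sample_rate),
                           nominal_freq=cfg.whisking_freq)
            for t in session.trials
        ]
    if decision is None:
        decision = decision_times(session)
    first_touches = [t.touch_events[0].onset if t.touch_events else np.nan
                     for t in session.trials]
    touched = np.isfinite(first_touches)
    if not touched.any():
        raise ValueError("session has no touch trials: median first-touch "
                         "time undefined")
    median_ft = float(np.median(np.asarray(first_touches)[touched]))

    pre_t, pre_n, post_t, post_n = [], [], [], []
    for i, (trial, whisks) in enumerate(zip(session.trials, whisks_per_trial)):
        ft = first_touches[i] if touched[i] else median_ft
        peaks = np.array([w.peak_time for w in whisks])
        pre = int(np.sum((peaks >= cfg.pole_trigger_time) & (peaks < ft)))
        post = int(np.sum((peaks >= ft) & (peaks < decision[i])))
        (pre_t if touched[i] else pre_n).append(pre)
        (post_t if touched[i] else post_n).append(post)

    def kl_between(a, b):
        a, b = np.asarray(a), np.asarray(b)
        if a.size == 0 or b.size == 0:
            return float("nan")
        n_bins = int(max(a.max(initial=0), b.max(initial=0))) + 1
        return kl_divergence(_count_hist(a, n_bins), _count_hist(b, n_bins))

    return WhiskCountResult(
        pre_counts_touch=np.asarray(pre_t), pre_counts_notouch=np.asarray(pre_n),
        post_counts_touch=np.asarray(post_t), post_counts_notouch=np.asarray(post_n),
        kl_pre=kl_between(pre_t, pre_n), kl_post=kl_between(post_t, post_n),
        median_first_touch=median_ft,
    )


def lick_probability_by_touch_count(
    session: Session,
    normalize_by_position: bool = False,
    min_trials: int = 5,
    position_bin_width: float = 1.0,
) -> pd.DataFrame:
    """Lick probability conditioned on pre-decision touch count, per trial type.

    Unnormalized mode: one row per (trial type, exact touch count).
    Normalized mode: per-trial touch count minus the mean count of that
    trial's pole-position bin, rounded to integer bins. Counts backed by
    fewer than ``min_trials`` trials are suppressed.
    """
    dts = decision_times(session)
    rows = []
    for trial, dt in zip(session.trials, dts):
        n = sum(1 for e in trial.touch_events if e.onset < dt)
        rows.append([trial.trial_type, trial.pole_position, n,
                     1.0 if trial.choice == LICK else 0.0])
    df = pd.DataFrame(rows, columns=["trial_type", "position", "count", "lick"])
    if normalize_by_position:
        bins = np.floor(df["position"] / position_bin_width)
        df["count"] = np.round(
            df["count"] - df.groupby(bins)["count"].transform("mean")).astype(int)
    out = (df.groupby(["trial_type", "count"])
             .agg(lick_probability=("lick", "mean"), n_trials=("lick", "size"))
             .reset_index())
    return out[out["n_trials"] >= min_trials].reset_index(drop=True)


def protraction_targeting(
    session: Session,
    whisks_per_trial: Optional[Sequence[Sequence[Whisk]]] = None,
    decision: Optional[np.ndarray] = None,
    max_whisks: int = 10,
) -> pd.DataFrame:
    """Peak protraction relative to the discrimination boundary, by whisk
    index and trial type (pre-decision whisks only). SD is missing where a
    cell has fewer than two whisks."""
    cfg = session.config
    theta_b = boundary_angle(cfg)
    if whisks_per_trial is None:
        whisks_per_trial = [
            segment_whisks(hilbert_decompose(t.angle_series, cfg.sample_rate),
                           nominal_freq=cfg.whisking_freq)
            for t in session.trials
        ]
    if decision is None:
        decision = decision_times(session)
    cells: Dict[Tuple[str, int], List[float]] = {}
    for trial, whisks, dt in zip(session.trials, whisks_per_trial, decision):
        pre = [w for w in whisks if w.peak_time < dt]
        for k, w in enumerate(pre[:max_whisks]):
            cells.setdefault((trial.trial_type, k), []).append(
                w.peak_protraction - theta_b)
    rows = []
    for (tt, k), vals in sorted(cells.items()):
        arr = np.asarray(vals)
        sd = float(arr.std(ddof=1)) if arr.size > 1 else np.nan
        rows.append([tt, k, float(arr.mean()), sd, arr.size])
    return pd.DataFrame(rows, columns=["trial_type", "whisk_index",
                                       "mean_peak_rel_boundary", "sd", "n"])


def resolution_comparison(
    subject_curve: PsychometricCurve,
    classifier_curves: Sequence[PsychometricCurve],
) -> pd.DataFrame:
    """Per-bin |classifier - subject| lick probability and a summed deviation
    score per classifier; a lower score is a better behavioral match."""
    rows = []
    for curve in classifier_curves:
        if not np.array_equal(curve.bin_edges, subject_curve.bin_edges):
            raise ValueError("classifier curve bins do not match subject bins")
        dev = np.abs(curve.lick_probability - subject_curve.lick_probability)
        for center, d in zip(curve.bin_centers, dev):
            rows.append([curve.target, float(center), float(d)])
        rows.append([curve.target, np.nan, float(np.nansum(dev))])
    return pd.DataFrame(rows, columns=["classifier", "bin_center", "deviation"])
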