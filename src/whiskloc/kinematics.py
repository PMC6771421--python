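"""Whisking kinematics: band-pass filtering, Hilbert decomposition, whisk
segmentation, component autocorrelation, and a discrete KL divergence.

The whisker azimuthal angle is decomposed into three components with distinct
timescales: an instantaneous amplitude envelope and phase from the analytic
signal of the 6-60 Hz band-passed angle, and a slowly varying midpoint (the
offset about which the whisker oscillates) obtained as the low-passed
remainder ``raw - bandpassed``. Filtering is zero-phase (forward-backward
Butterworth), so event times sampled from the components are not shifted.
The first and last 100 ms of a trial are flagged as filter transients and
excluded from component statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal

EDGE_TRANSIENT_MS = 100.0
DEFAULT_BAND = (6.0, 60.0)
DEFAULT_FILTER_ORDER = 4
WHISK_AMPLITUDE_THRESHOLD = 5.0  # deg


@dataclass
class KinematicDecomposition:
    """Per-trial angle decomposition: angle = midpoint + bandpassed + residual,
    with bandpassed = amplitude * cos(phase)."""

    angle: np.ndarray
    bandpassed: np.ndarray
    amplitude: np.ndarray     # deg, >= 0
    midpoint: np.ndarray      # deg
    phase: np.ndarray         # rad, in (-pi, pi]
    sample_rate: float        # Hz

    @property
    def n(self) -> int:
        return self.angle.size

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n) * 1000.0 / self.sample_rate

    @property
    def interior(self) -> np.ndarray:
        """Boolean mask excluding the edge filter transients."""
        edge = int(round(EDGE_TRANSIENT_MS * self.sample_rate / 1000.0))
        mask = np.zeros(self.n, dtype=bool)
        if self.n > 2 * edge:
            mask[edge:self.n - edge] = True
        return mask

    def index_at(self, time_ms: float) -> int:
        idx = int(round(time_ms * self.sample_rate / 1000.0))
        return min(max(idx, 0), self.n - 1)

    def trough_times(self) -> np.ndarray:
        """Times (ms) of whisking troughs, defined as phase wraps through -pi."""
        wraps = np.nonzero(np.diff(self.phase) < -np.pi)[0] + 1
        return wraps * 1000.0 / self.sample_rate


@dataclass
class Whisk:
    """One whisk cycle: trough -> peak -> next trough."""

    trough_time: float        # ms
    peak_time: float          # ms
    next_trough_time: float   # ms
    peak_protraction: float   # deg, raw angle at the peak
    whisk_amplitude: float    # deg, instantaneous amplitude at the peak


def bandpass(
    angle_series: np.ndarray,
    sample_rate: float,
    low: float = DEFAULT_BAND[0],
    high: float = DEFAULT_BAND[1],
    order: int = DEFAULT_FILTER_ORDER,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass, same length as the input."""
    x = np.asarray(angle_series, dtype=float)
    if sample_rate <= 2 * high:
        raise ValueError(f"sample_rate must exceed 2*high = {2 * high} Hz")
    min_len = 3 * (2 * order + 1)
    if x.size <= min_len:
        raise ValueError(
            f"series of length {x.size} too short for order-{order} "
            f"band-pass (need > {min_len} samples)"
        )
    sos = signal.butter(order, [low, high], btype="bandpass", fs=sample_rate,
                        output="sos")
    return signal.sosfiltfilt(sos, x)


def _lowpass(x: np.ndarray, sample_rate: float, cutoff: float, order: int = 2) -> np.ndarray:
    sos = signal.butter(order, cutoff, btype="lowpass", fs=sample_rate, output="sos")
    return signal.sosfiltfilt(sos, x)


def hilbert_decompose(
    angle_series: np.ndarray,
    sample_rate: float,
    low: float = DEFAULT_BAND[0],
    high: float = DEFAULT_BAND[1],
    order: int = DEFAULT_FILTER_ORDER,
) -> KinematicDecomposition:
    """Decompose a whisker angle series into amplitude, midpoint and phase.

    Amplitude is the modulus and phase the argument of the analytic signal of
    the band-passed angle; midpoint is the remainder ``raw - bandpassed``
    low-pass smoothed below the whisking band.

    Raises ``ValueError`` naming the first offending index if the input
    contains NaN.
    """
    x = np.asarray(angle_series, dtype=float)
    bad = np.nonzero(~np.isfinite(x))[0]
    if bad.size:
        raise ValueError(f"non-finite angle sample at index {bad[0]}")
    bp = bandpass(x, sample_rate, low=low, high=high, order=order)
    analytic = signal.hilbert(bp)
    amplitude = np.abs(analytic)
    phase = np.angle(analytic)
    phase[phase == -np.pi] = np.pi  # half-open convention (-pi, pi]
    midpoint = _lowpass(x - bp, sample_rate, cutoff=low)
    return KinematicDecomposition(
        angle=x, bandpassed=bp, amplitude=amplitude, midpoint=midpoint,
        phase=phase, sample_rate=sample_rate,
    )


def segment_whisks(
    decomposition: KinematicDecomposition,
    amplitude_threshold: float = WHISK_AMPLITUDE_THRESHOLD,
    min_separation_ms: Optional[float] = None,
    nominal_freq: float = 15.0,
) -> List[Whisk]:
    """Segment whisk cycles from a decomposition.

    One whisk per local maximum of the band-passed angle whose instantaneous
    whisking amplitude reaches ``amplitude_threshold`` (5 degrees by
    default). Peaks closer than half the nominal whisk period are merged
    (earliest-sample tie-break is scipy's plateau convention). Peaks inside
    the edge transients or without flanking troughs are dropped.
    """
    fs = decomposition.sample_rate
    if min_separation_ms is None:
        min_separation_ms = 0.5 * 1000.0 / nominal_freq
    distance = max(int(round(min_separation_ms * fs / 1000.0)), 1)
    bp = decomposition.bandpassed
    peaks, _ = signal.find_peaks(bp, distance=distance)
    troughs, _ = signal.find_peaks(-bp, distance=distance)
    if peaks.size == 0 or troughs.size == 0:
        return []
    interior = decomposition.interior
    whisks: List[Whisk] = []
    for p in peaks:
        if not interior[p]:
            continue
        if decomposition.amplitude[p] < amplitude_threshold:
            continue
        before = troughs[troughs < p]
        after = troughs[troughs > p]
        if before.size == 0 or after.size == 0:
            continue
        whisks.append(Whisk(
            trough_time=before[-1] * 1000.0 / fs,
            peak_time=p * 1000.0 / fs,
            next_trough_time=after[0] * 1000.0 / fs,
            peak_protraction=float(decomposition.angle[p]),
            whisk_amplitude=float(decomposition.amplitude[p]),
        ))
    return whisks


def component_autocorrelation(
    series: np.ndarray,
    max_lag_ms: float,
    sample_rate: float = 1000.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Normalized autocorrelation of a mean-subtracted series.

    Returns ``(lags_ms, r)`` with ``r[0] == 1``. A zero-variance series is
    defined as 1 at lag 0 and 0 elsewhere, with a warning.
    """
    x = np.asarray(series, dtype=float)
    x = x - x.mean()
    max_lag = int(round(max_lag_ms * sample_rate / 1000.0))
    max_lag = min(max_lag, x.size - 1)
    lags = np.arange(max_lag + 1) * 1000.0 / sample_rate
    denom = float(np.dot(x, x))
    if denom == 0.0:
        warnings.warn("zero-variance series: autocorrelation defined as delta at lag 0")
        r = np.zeros(max_lag + 1)
        r[0] = 1.0
        return lags, r
    r = np.empty(max_lag + 1)
    r[0] = 1.0
    for k in range(1, max_lag + 1):
        r[k] = float(np.dot(x[:-k], x[k:])) / denom
    return lags, r


def kl_divergence(p: Sequence[float], q: Sequence[float]) -> float:
    """Discrete Kullback-Leibler divergence sum(p * ln(p/q)) in nats.

    Inputs are normalized to probability vectors over the same support.
    Bins where ``q`` is empty but ``p`` is not are smoothed by adding
    ``1/(10*n)`` (n = number of bins) to the empty ``q`` bins before
    renormalizing.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"distributions have different shapes: {p.shape} vs {q.shape}")
    if p.sum() <= 0 or q.sum() <= 0:
        raise ValueError("distributions must have positive mass")
    if np.any(p < 0) or np.any(q < 0):
        raise ValueError("distributions must be non-negative")
    p = p / p.sum()
    q = q / q.sum()
    empty = (q == 0) & (p > 0)
    if np.any(empty):
        eps = 1.0 / (10.0 * p.size)
        q = q + np.where(empty, eps, 0.0)
        q = q / q.sum()
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))
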