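"""Utterance-level signal conditioning and augmentation.

Implements the preprocessing contract of the word decoder: moving-average
smoothing (window 5), the 100-220 step validity window, symmetric zero
padding to 220 steps, z-score normalization with training-corpus statistics,
the three stochastic augmentations applied in training (time warping by index
duplication, random 200-step cropping, uniform amplitude scaling), and
energy-based voice activity detection on an unbounded strain stream.

Sequences are (T, C) arrays: T time steps at the 50 Hz frame rate, C strain
feature channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "NormStats",
    "VADSegment",
    "smooth",
    "validate_length",
    "center_pad",
    "fit_norm",
    "apply_norm",
    "StrainNormalizer",
    "augment_time_warp",
    "augment_crop",
    "augment_scale",
    "detect_voice_activity",
]

VALID_LENGTH_BOUNDS = (100, 220)
PAD_TARGET = 220
CROP_LENGTH = 200


def _as_seq(seq) -> np.ndarray:
    arr = np.asarray(seq, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.ndim != 2 or arr.shape[0] < 1:
        raise ValueError("expected a (T, C) sequence with T >= 1")
    return arr


def smooth(seq, window: int = 5) -> np.ndarray:
    """Centered per-channel moving average; edges use a shrinking window."""
    arr = _as_seq(seq)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > arr.shape[0]:
        raise ValueError("window exceeds sequence length")
    kernel = np.ones(window)
    counts = np.convolve(np.ones(arr.shape[0]), kernel, mode="same")
    out = np.empty_like(arr)
    for c in range(arr.shape[1]):
        out[:, c] = np.convolve(arr[:, c], kernel, mode="same") / counts
    return out


def validate_length(seq, bounds: tuple[int, int] = VALID_LENGTH_BOUNDS) -> bool:
    """True iff the sequence length lies in the inclusive validity window."""
    arr = _as_seq(seq)
    lo, hi = bounds
    return lo <= arr.shape[0] <= hi


def center_pad(seq, target: int = PAD_TARGET) -> np.ndarray:
    """Symmetric zero padding to ``target`` steps; odd remainder trails.

    The original values stay contiguous and centered, so the per-channel sum
    is conserved exactly.
    """
    arr = _as_seq(seq)
    T = arr.shape[0]
    if T > target:
        raise ValueError(f"sequence length {T} exceeds pad target {target}")
    lead = (target - T) // 2
    trail = target - T - lead
    return np.pad(arr, ((lead, trail), (0, 0)))


@dataclass
class NormStats:
    """Training-corpus normalization statistics (global or per-channel)."""

    mu: np.ndarray | float
    sigma: np.ndarray | float


def fit_norm(corpus, per_channel: bool = False, eps: float = 0.0) -> NormStats:
    """Mean/SD of the training corpus; global scalars by default.

    ``corpus`` is an iterable of (T, C) sequences (lengths may differ).
    A constant corpus has zero SD and raises unless ``eps`` > 0 guards it.
    """
    seqs = [_as_seq(s) for s in corpus]
    if not seqs:
        raise ValueError("corpus must be non-empty")
    stacked = np.concatenate(seqs, axis=0)
    if per_channel:
        mu = stacked.mean(axis=0)
        sigma = stacked.std(axis=0)
    else:
        mu = float(stacked.mean())
        sigma = float(stacked.std())
    if np.any(np.asarray(sigma) + eps <= 0):
        raise ValueError("zero variance in corpus; enable an epsilon guard")
    return NormStats(mu=mu, sigma=np.asarray(sigma) + eps if eps else sigma)


def apply_norm(seq, stats: NormStats) -> np.ndarray:
    """Affine z-score map x -> (x - mu_train) / sigma_train."""
    return (_as_seq(seq) - stats.mu) / stats.sigma


class StrainNormalizer(BaseEstimator, TransformerMixin):
    """z-score normalization with training-set statistics, estimator-style.

    ``fit`` computes global (or per-channel) mean/SD over a list or array of
    sequences; ``transform`` applies the affine map to each sequence.
    """

    def __init__(self, per_channel: bool = False, eps: float = 0.0):
        self.per_channel = per_channel
        self.eps = eps

    def fit(self, X, y=None):
        seqs = list(X) if not isinstance(X, np.ndarray) or X.ndim != 3 else [x for x in X]
        stats = fit_norm(seqs, per_channel=self.per_channel, eps=self.eps)
        self.mu_ = stats.mu
        self.sigma_ = stats.sigma
        return self

    def transform(self, X):
        stats = NormStats(self.mu_, self.sigma_)
        if isinstance(X, np.ndarray) and X.ndim == 3:
            return np.stack([apply_norm(x, stats) for x in X])
        return [apply_norm(x, stats) for x in X]


def augment_time_warp(
    seq,
    n_dup: int = 20,
    active_range: tuple[int, int] = (20, 200),
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Local time dilation: duplicate values at sampled active indices.

    ``n_dup`` indices are sampled without replacement from
    ``[active_range[0], active_range[1])`` and their values duplicated in
    place, stretching the temporal axis while preserving order.  Output
    length is T + n_dup.
    """
    arr = _as_seq(seq)
    lo, hi = active_range
    if arr.shape[0] < hi:
        raise ValueError(f"sequence shorter than active range upper bound {hi}")
    rng = np.random.default_rng() if rng is None else rng
    idx = rng.choice(np.arange(lo, hi), size=n_dup, replace=False)
    repeats = np.ones(arr.shape[0], dtype=int)
    repeats[idx] += 1
    return np.repeat(arr, repeats, axis=0)


def augment_crop(seq, out_len: int = CROP_LENGTH, rng: np.random.Generator | None = None) -> np.ndarray:
    """Random contiguous window of ``out_len`` steps (temporal shift invariance)."""
    arr = _as_seq(seq)
    T = arr.shape[0]
    if T < out_len:
        raise ValueError(f"sequence length {T} below crop length {out_len}")
    rng = np.random.default_rng() if rng is None else rng
    start = int(rng.integers(0, T - out_len + 1))
    return arr[start : start + out_len].copy()


def augment_scale(
    seq,
    bounds: tuple[float, float] = (0.9, 1.1),
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Multiplicative amplitude noise: one alpha ~ U(bounds) per call."""
    if not bounds[0] < bounds[1]:
        raise ValueError("bounds must be increasing")
    arr = _as_seq(seq)
    rng = np.random.default_rng() if rng is None else rng
    alpha = rng.uniform(*bounds)
    return arr * alpha


@dataclass
class VADSegment:
    """A detected utterance span [start, end) with its peak window energy."""

    start: int
    end: int
    peak_energy: float


def _stream_energy(arr: np.ndarray, window: int) -> np.ndarray:
    """Trailing boxcar energy: sum of squared channel norms over the last
    ``window`` samples at each index."""
    sq = (arr**2).sum(axis=1)
    c = np.concatenate([[0.0], np.cumsum(sq)])
    idx = np.arange(1, len(sq) + 1)
    lo = np.maximum(idx - window, 0)
    return c[idx] - c[lo]


def detect_voice_activity(
    stream,
    window: int = 200,
    threshold: float | None = None,
    length_bounds: tuple[int, int] = VALID_LENGTH_BOUNDS,
    calibration: int = 400,
) -> list[VADSegment]:
    """Energy-gated utterance segmentation of a strain stream.

    The running energy is the trailing ``window``-sample sum of squared
    channel norms.  Energy rising above ``threshold`` opens a detection
    event; falling below closes it.  Because the trailing window lags the
    underlying activity, the reported boundaries are refined inside the gated
    span: the start (end) is the first (last) sample whose instantaneous
    power exceeds the larger of ``threshold / window`` and half the event's
    peak mean power.  Segments whose refined length falls outside
    ``length_bounds`` are discarded.

    With ``threshold=None`` the threshold is calibrated per stream as
    mu + 4*sigma of the energy over the leading ``calibration`` samples.
    """
    arr = _as_seq(stream)
    energy = _stream_energy(arr, window)
    if threshold is None:
        lead = energy[: max(min(calibration, len(energy)), 1)]
        threshold = float(lead.mean() + 4.0 * lead.std())
        if threshold <= 0:
            threshold = 1e-12
    if threshold <= 0:
        raise ValueError("threshold must be > 0")

    power = (arr**2).sum(axis=1)
    active = energy > threshold
    segments: list[VADSegment] = []
    t = 0
    n = len(active)
    while t < n:
        if not active[t]:
            t += 1
            continue
        t_up = t
        while t < n and active[t]:
            t += 1
        t_down = t  # first index with energy back below threshold (or n)
        span_lo = max(t_up - window, 0)
        span_hi = t_down
        peak = float(energy[t_up:t_down].max()) if t_down > t_up else float(energy[t_up])
        # boundary refinement threshold: at least half the mean in-burst power,
        # so a near-noise gate threshold does not sweep noise into the segment
        sample_thr = max(threshold / window, 0.5 * peak / window)
        gate = power[span_lo:span_hi] > sample_thr
        hits = np.flatnonzero(gate)
        if len(hits) == 0:
            continue
        start = span_lo + int(hits[0])
        end = span_lo + int(hits[-1]) + 1
        lo, hi = length_bounds
        if lo <= end - start <= hi:
            segments.append(VADSegment(start=start, end=end, peak_energy=float(energy[t_up:t_down].max())))
    return segments
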