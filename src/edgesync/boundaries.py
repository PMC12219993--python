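"""Boundary regressors and lag analyses relating events to scene endings.

Coded movie-scene (or trailer) endings are represented as unit impulses and
convolved with a canonical double-gamma hemodynamic response function so
that stimulus timing can be compared with BOLD-derived event series at the
hemodynamic delay.  Lagged correlations, peri-boundary profiles, and a
windowed circular-shift test quantify the alignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .events import EventSeries

__all__ = [
    "BoundaryAnnotation",
    "LagProfile",
    "canonical_hrf",
    "convolve_boundaries",
    "lagged_correlation",
    "peri_boundary_profile",
    "windowed_shift_test",
]

HRF_DURATION_SECONDS = 32.0


@dataclass
class BoundaryAnnotation:
    """Coded scene-ending frames and their HRF-convolved regressor."""

    ending_frames: np.ndarray
    regressor: np.ndarray
    tr_seconds: float

    @property
    def n_frames(self) -> int:
        return self.regressor.shape[0]


@dataclass
class LagProfile:
    """A value (correlation, probability, or mean amplitude) per time lag."""

    lags_seconds: np.ndarray
    values: np.ndarray
    n_observations: np.ndarray | None = None

    def peak_lag(self) -> float:
        """Lag (seconds) at which the profile is maximal."""
        return float(self.lags_seconds[int(np.nanargmax(self.values))])


def canonical_hrf(
    tr: float,
    peak_shape: float = 6.0,
    undershoot_shape: float = 16.0,
    undershoot_ratio: float = 1.0 / 6.0,
    duration: float = HRF_DURATION_SECONDS,
) -> np.ndarray:
    """Canonical double-gamma HRF sampled at the TR, normalized to unit peak.

    The kernel is the difference of two gamma densities (shapes 6 and 16,
    unit scale, undershoot weighted 1/6), the de-facto standard response
    shape, peaking near 5 s after the impulse.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    if tr >= duration:
        raise ValueError(f"tr={tr} is not smaller than the kernel duration {duration} s")
    t = np.arange(0.0, duration, tr)
    kernel = stats.gamma.pdf(t, peak_shape) - undershoot_ratio * stats.gamma.pdf(t, undershoot_shape)
    return kernel / kernel.max()


def hrf_peak_lag_seconds(tr: float, **hrf_kwargs) -> float:
    """Lag of the sampled HRF maximum, in seconds."""
    kernel = canonical_hrf(tr, **hrf_kwargs)
    return float(np.argmax(kernel) * tr)


def convolve_boundaries(
    endings: Sequence[int] | np.ndarray,
    n_frames: int,
    tr: float,
    **hrf_kwargs,
) -> BoundaryAnnotation:
    """Unit impulses at ending frames convolved with the canonical HRF."""
    endings = np.asarray(endings, dtype=int)
    if endings.size and (endings.min() < 0 or endings.max() >= n_frames):
        raise ValueError("ending frames must lie in [0, n_frames)")
    if endings.size > 1 and np.any(np.diff(endings) <= 0):
        raise ValueError("ending frames must be strictly increasing")
    impulses = np.zeros(n_frames)
    impulses[endings] = 1.0
    kernel = canonical_hrf(tr, **hrf_kwargs)
    regressor = np.convolve(impulses, kernel)[:n_frames]
    return BoundaryAnnotation(ending_frames=endings, regressor=regressor, tr_seconds=tr)


def lagged_correlation(
    x: np.ndarray,
    y: np.ndarray,
    lag_range_seconds: tuple[float, float] = (-20.0, 40.0),
    tr: float = 1.0,
    min_overlap: int = 10,
) -> LagProfile:
    """Pearson correlation of ``y`` against ``x`` across integer-frame lags.

    A lag of +k seconds delays ``y`` by k relative to ``x``: the value at lag
    k is ``corr(x[:T-k], y[k:])``, so a series that trails its driver peaks
    at a positive lag.  No wraparound — only the overlapping segment is
    used, and lags with fewer than ``min_overlap`` overlapping frames are
    dropped with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    T = x.shape[0]
    lo, hi = lag_range_seconds
    if not lo < hi:
        raise ValueError("lag range lower bound must be below upper bound")
    lag_frames = np.arange(int(round(lo / tr)), int(round(hi / tr)) + 1)
    lags, values = [], []
    dropped = 0
    for k in lag_frames:
        if k >= 0:
            xs, ys = x[: T - k], y[k:]
        else:
            xs, ys = x[-k:], y[: T + k]
        if xs.shape[0] < min_overlap:
            dropped += 1
            continue
        if xs.std() == 0 or ys.std() == 0:
            values.append(np.nan)
        else:
            values.append(float(np.corrcoef(xs, ys)[0, 1]))
        lags.append(k * tr)
    if dropped:
        warnings.warn(f"{dropped} lag(s) dropped: overlap shorter than {min_overlap} frames")
    return LagProfile(lags_seconds=np.asarray(lags), values=np.asarray(values))


def peri_boundary_profile(
    series: Iterable[np.ndarray],
    endings: Sequence[int] | np.ndarray,
    window_seconds: tuple[float, float] = (-20.0, 40.0),
    tr: float = 1.0,
) -> LagProfile:
    """Event probability (or mean amplitude) as a function of lag from endings.

    For every lag in the window, values are pooled across all subjects and
    all endings; binary inputs yield the fraction of (subject, ending) pairs
    with an event at that lag, continuous inputs yield the mean.  Lags that
    fall outside a scan for a given ending are skipped for that ending.
    """
    endings = np.asarray(endings, dtype=int)
    lag_frames = np.arange(int(round(window_seconds[0] / tr)), int(round(window_seconds[1] / tr)) + 1)
    sums = np.zeros(lag_frames.shape[0])
    counts = np.zeros(lag_frames.shape[0])
    for vec in series:
        vec = np.asarray(vec, dtype=float)
        T = vec.shape[0]
        for b in endings:
            pos = b + lag_frames
            ok = (pos >= 0) & (pos < T)
            sums[ok] += vec[pos[ok]]
            counts[ok] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return LagProfile(lags_seconds=lag_frames * tr, values=values, n_observations=counts.astype(int))


def windowed_shift_test(
    events: Sequence[EventSeries] | Sequence[np.ndarray],
    endings: Sequence[int] | np.ndarray,
    window_seconds: float = 10.0,
    n_shifts: int = 100,
    seed: int | np.random.Generator | None = None,
    tr: float = 1.0,
) -> float:
    """Are there more events near endings than chance?  One p-value per scan.

    The observed statistic is the total event count (over subjects) inside
    a +/- ``window_seconds`` window around every ending.  Under the null the
    window positions are circularly shifted by a shared uniform offset,
    ``n_shifts`` times; p = (1 + #{null >= observed}) / (1 + n_shifts).
    """
    if n_shifts < 1:
        raise ValueError("n_shifts must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mats = [e.frames if isinstance(e, EventSeries) else np.asarray(e) for e in events]
    stacked = np.asarray(mats)  # (S, T)
    T = stacked.shape[1]
    counts_per_frame = stacked.sum(axis=0)
    half = int(round(window_seconds / tr))
    endings = np.asarray(endings, dtype=int)

    def in_window_count(offset: int) -> int:
        mask = np.zeros(T, dtype=bool)
        for b in (endings + offset) % T:
            lo, hi = b - half, b + half + 1
            idx = np.arange(lo, hi) % T
            mask[idx] = True
        return int(counts_per_frame[mask].sum())

    observed = in_window_count(0)
    null = np.array([in_window_count(int(o)) for o in rng.integers(0, T, size=n_shifts)])
    return float((1 + np.sum(null >= observed)) / (1 + n_shifts))
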