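"""Per-scan detection of high-amplitude co-fluctuation frames ("events").

A scan's observed RSS trace is compared against a surrogate null built by
independently circularly shifting each node's z-scored time series: shifting
preserves every node's autocorrelation and marginal moments while destroying
the inter-node temporal alignment that produces genuine co-fluctuation.
Frames whose RSS exceeds the pooled-null percentile threshold are
supra-threshold; each maximal supra-threshold run is collapsed to its peak
frame, and those peaks are the scan's events.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .edgets import ParcelTimeSeries, RSSSeries, _zscore_matrix, rss_from_zscores

__all__ = ["NullRSS", "EventSeries", "null_rss", "detect_events", "event_rate"]


@dataclass
class NullRSS:
    """Pooled circular-shift null distribution of RSS values."""

    values: np.ndarray
    threshold: float
    percentile: float
    n_null: int
    seed: int | None = None


@dataclass
class EventSeries:
    """Binary event indicator for one scan.

    ``frames`` marks detected frames (by default only run peaks);
    ``peak_frames`` lists one peak per maximal supra-threshold run.
    """

    frames: np.ndarray
    peak_frames: np.ndarray
    alpha: float
    n_null: int
    seed: int | None = None
    tr_seconds: float = 1.0

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def null_rss(
    ts: ParcelTimeSeries,
    n_null: int = 100,
    seed: int | np.random.Generator | None = None,
    alpha: float = 0.05,
    offsets: np.ndarray | None = None,
) -> NullRSS:
    """Build the circular-shift RSS null for one scan.

    For each of ``n_null`` realizations every node's z-scored series is
    circularly shifted by an independent uniform offset and the RSS trace is
    recomputed; all T*n_null values are pooled and the detection threshold is
    the (1-alpha) percentile of the pool.

    ``offsets`` is a testing hook: an (n_null, N) integer array of forced
    shift offsets (0 reproduces the observed RSS exactly).
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Z = _zscore_matrix(ts.data, ts.node_labels)
    T, N = Z.shape
    if offsets is None:
        offsets = rng.integers(0, T, size=(n_null, N))
    else:
        offsets = np.asarray(offsets, dtype=int)
        if offsets.shape != (n_null, N):
            raise ValueError("offsets must have shape (n_null, n_nodes)")
    # RSS depends on Z only through per-frame sums of z^2 and z^4, so the
    # shifted realizations never need the O(N^2) edge matrix.
    Z2, Z4 = Z**2, Z**4
    t_idx = np.arange(T)[:, None]
    cols = np.arange(N)[None, :]
    pooled = np.empty((n_null, T))
    for k in range(n_null):
        idx = (t_idx - offsets[k][None, :]) % T
        s2 = Z2[idx, cols].sum(axis=1)
        s4 = Z4[idx, cols].sum(axis=1)
        pooled[k] = np.sqrt(np.maximum(s2**2 - s4, 0.0) / 2.0)
    values = pooled.ravel()
    pct = (1.0 - alpha) * 100.0
    threshold = float(np.percentile(values, pct))
    seed_out = seed if isinstance(seed, (int, np.integer)) else None
    return NullRSS(values=values, threshold=threshold, percentile=pct, n_null=n_null, seed=seed_out)


def _run_peaks(supra: np.ndarray, values: np.ndarray) -> np.ndarray:
    """One peak per maximal run of True; ties resolved to the earliest frame."""
    peaks = []
    T = supra.shape[0]
    t = 0
    while t < T:
        if supra[t]:
            start = t
            while t < T and supra[t]:
                t += 1
            seg = values[start:t]
            peaks.append(start + int(np.argmax(seg)))
        else:
            t += 1
    return np.asarray(peaks, dtype=int)


def detect_events(
    rss_series: RSSSeries,
    null: NullRSS,
    mark: str = "peak",
) -> EventSeries:
    """Threshold an RSS trace against its null and collapse runs to peaks.

    ``mark='peak'`` (default) sets the binary series at peak frames only;
    ``mark='run'`` marks every supra-threshold frame.
    """
    if mark not in ("peak", "run"):
        raise ValueError("mark must be 'peak' or 'run'")
    supra = rss_series.data > null.threshold
    peaks = _run_peaks(supra, rss_series.data)
    frames = np.zeros(rss_series.n_frames, dtype=int)
    if mark == "run":
        frames[supra] = 1
    elif peaks.size:
        frames[peaks] = 1
    alpha = 1.0 - null.percentile / 100.0
    return EventSeries(
        frames=frames,
        peak_frames=peaks,
        alpha=alpha,
        n_null=null.n_null,
        seed=null.seed,
        tr_seconds=rss_series.tr_seconds,
    )


def event_rate(events: EventSeries) -> float:
    """Events per minute of scan time."""
    total_seconds = events.n_frames * events.tr_seconds
    return len(events.peak_frames) * 60.0 / total_seconds
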