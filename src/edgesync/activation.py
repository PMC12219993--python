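"""Node-level activation correlates of boundary events.

Because a co-fluctuation matrix is invariant to a global sign flip of the
activity pattern that generated it, edge-level results cannot by themselves
reveal whether boundary events reflect activation or deactivation.  This
module correlates each node's activity with the binary boundary-frame
indicator, tests system-level concentration of those correlations with a
spin (or label-permutation) null, and tests inter-subject stability of the
activation map against a circular time-shift null.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from ._spatial import spatial_permutations
from .boundaries import canonical_hrf
from .edgets import ParcelTimeSeries
from .synchrony import BOUNDARY, FrameClassification

__all__ = [
    "ActivationMap",
    "boundary_indicator",
    "activation_map",
    "system_test",
    "stability_test",
]


@dataclass
class ActivationMap:
    """Per-node correlation of activity with the boundary-event indicator."""

    values: np.ndarray
    system_labels: list[str]
    p_values: np.ndarray | None = None
    p_bonferroni: np.ndarray | None = None


def boundary_indicator(
    frames: FrameClassification | Sequence[int] | np.ndarray,
    n_frames: int | None = None,
    tr: float = 1.0,
    hrf_convolve: bool = False,
) -> np.ndarray:
    """Binary vector marking boundary-class frames.

    Accepts a classified ``FrameClassification`` or an explicit list of
    boundary frames.  The raw binary indicator is the default: frame labels
    already absorb hemodynamic lag.  ``hrf_convolve=True`` returns the
    HRF-convolved version for sensitivity analyses.
    """
    if isinstance(frames, FrameClassification):
        if frames.labels is None:
            raise ValueError("frames must be classified first")
        ind = (frames.labels == BOUNDARY).astype(float)
    else:
        if n_frames is None:
            raise ValueError("n_frames is required with an explicit frame list")
        ind = np.zeros(n_frames)
        ind[np.asarray(frames, dtype=int)] = 1.0
    if hrf_convolve:
        ind = np.convolve(ind, canonical_hrf(tr))[: ind.shape[0]]
    return ind


def activation_map(ts: ParcelTimeSeries, indicator: np.ndarray) -> ActivationMap:
    """Per-node Pearson r between activity and the indicator, with p-values.

    p is the standard t-transform p for a correlation; a Bonferroni-adjusted
    p across the N nodes is reported alongside.
    """
    indicator = np.asarray(indicator, dtype=float)
    if indicator.shape[0] != ts.n_frames:
        raise ValueError("indicator length must equal the frame count")
    if indicator.std() == 0:
        raise ValueError("indicator is constant; correlation undefined")
    T, N = ts.data.shape
    zi = (indicator - indicator.mean()) / indicator.std(ddof=1)
    sd = ts.data.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("zero-variance node activity")
    Z = (ts.data - ts.data.mean(axis=0)) / sd
    r = (Z.T @ zi) / (T - 1)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((T - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=T - 2)
    return ActivationMap(
        values=r,
        system_labels=list(ts.system_labels),
        p_values=p,
        p_bonferroni=np.minimum(p * N, 1.0),
    )


def system_test(
    amap: ActivationMap,
    centroids: np.ndarray | None = None,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> dict[str, float]:
    """Two-sided permutation p per system for its mean map value.

    With centroids the null permutes nodes by random sphere rotations (spin
    test); otherwise size-preserving random label permutations are used.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = np.asarray(amap.values, dtype=float)
    systems = list(dict.fromkeys(amap.system_labels))
    sys_of_node = np.array([systems.index(s) for s in amap.system_labels])
    K = len(systems)
    counts = np.bincount(sys_of_node, minlength=K)
    observed = np.bincount(sys_of_node, weights=values, minlength=K) / counts

    perms = spatial_permutations(values.shape[0], n_perm, rng, centroids)
    null = np.empty((n_perm, K))
    for k in range(n_perm):
        null[k] = np.bincount(sys_of_node, weights=values[perms[k]], minlength=K) / counts
    center = null.mean(axis=0)
    n_ge = np.sum(np.abs(null - center) >= np.abs(observed - center)[None, :], axis=0)
    p = (1.0 + n_ge) / (1.0 + n_perm)
    return dict(zip(systems, p.tolist()))


def stability_test(
    scans: Sequence[ParcelTimeSeries],
    indicator: np.ndarray,
    n_shifts: int = 100,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float, list[ActivationMap]]:
    """Inter-subject similarity of activation maps vs a time-shifted null.

    The observed statistic is the mean pairwise correlation of subjects'
    maps.  Each null realization recomputes every subject's map after
    independently circularly shifting that subject's indicator, breaking
    stimulus alignment while preserving the indicator's structure.
    Returns (observed mean r, p, per-subject maps).
    """
    if len(scans) < 2:
        raise ValueError("stability test needs at least 2 subjects")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    indicator = np.asarray(indicator, dtype=float)

    def mean_pairwise_r(maps: np.ndarray) -> float:
        C = np.corrcoef(maps)
        iu = np.triu_indices(C.shape[0], k=1)
        return float(C[iu].mean())

    maps = [activation_map(ts, indicator) for ts in scans]
    observed = mean_pairwise_r(np.vstack([m.values for m in maps]))

    T = indicator.shape[0]
    null = np.empty(n_shifts)
    for k in range(n_shifts):
        shifted_maps = []
        for ts in scans:
            shifted = np.roll(indicator, int(rng.integers(0, T)))
            shifted_maps.append(activation_map(ts, shifted).values)
        null[k] = mean_pairwise_r(np.vstack(shifted_maps))
    p = float((1 + np.sum(null >= observed)) / (1 + n_shifts))
    return observed, p, maps
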