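"""Repeated-viewing analysis of a shared movie clip.

When the same clip is presented several times (across scans), each
(subject, viewing) segment is an aligned unit: events can be counted per
subject across viewings, per-frame synchrony can be tested with viewings as
units against a rest-based null, and the frame-wise similarity of
co-fluctuation patterns across viewings can be related to event synchrony.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.signal import find_peaks

from .edgets import EdgeSeries
from .events import EventSeries
from .synchrony import FrameClassification, GroupEventMatrix, synchrony_test

__all__ = [
    "ViewingStack",
    "align_clip",
    "viewing_counts",
    "viewing_synchrony",
    "frame_similarity",
    "synchrony_similarity_relation",
    "select_peaks",
    "peak_pattern_discrimination",
]


@dataclass
class ViewingStack:
    """Aligned clip segments: (subject, viewing) event and edge series.

    ``events`` is (S, V, T_clip) binary; ``edges`` is an optional matching
    nested list of clipped EdgeSeries for pattern-level analyses.
    """

    events: np.ndarray
    edges: list[list[EdgeSeries]] | None = None
    subject_ids: list[str] | None = None

    def __post_init__(self) -> None:
        if self.events.ndim != 3:
            raise ValueError("events must be (subjects, viewings, frames)")
        if self.n_viewings < 2:
            raise ValueError("need at least 2 viewings")
        if self.subject_ids is None:
            self.subject_ids = [f"sub{i:03d}" for i in range(self.events.shape[0])]

    @property
    def n_subjects(self) -> int:
        return self.events.shape[0]

    @property
    def n_viewings(self) -> int:
        return self.events.shape[1]

    @property
    def n_frames(self) -> int:
        return self.events.shape[2]


def align_clip(
    event_series: Sequence[Sequence[EventSeries]],
    clip_windows: Sequence[tuple[int, int]],
    edge_series: Sequence[Sequence[EdgeSeries]] | None = None,
) -> ViewingStack:
    """Restrict per-subject, per-viewing scans to the shared clip.

    ``clip_windows[v]`` is the half-open frame range [start, end) of the
    clip within viewing v's scan; all windows must have equal length.
    """
    lengths = {end - start for start, end in clip_windows}
    if len(lengths) != 1:
        raise ValueError(f"clip windows differ in length: {sorted(lengths)}")
    (t_clip,) = lengths
    if t_clip <= 0:
        raise ValueError("clip windows must be non-empty")
    S = len(event_series)
    V = len(clip_windows)
    ev = np.zeros((S, V, t_clip), dtype=int)
    for s in range(S):
        if len(event_series[s]) != V:
            raise ValueError("every subject needs one scan per viewing")
        for v, (start, end) in enumerate(clip_windows):
            series = event_series[s][v]
            if start < 0 or end > series.n_frames:
                raise ValueError(f"window [{start}, {end}) outside scan of {series.n_frames} frames")
            ev[s, v] = series.frames[start:end]
    edges = None
    if edge_series is not None:
        edges = [
            [
                EdgeSeries(
                    data=edge_series[s][v].data[start:end],
                    edge_index=edge_series[s][v].edge_index,
                    tr_seconds=edge_series[s][v].tr_seconds,
                )
                for v, (start, end) in enumerate(clip_windows)
            ]
            for s in range(S)
        ]
    return ViewingStack(events=ev, edges=edges)


def viewing_counts(stack: ViewingStack) -> np.ndarray:
    """How many of a subject's viewings had an event at each frame (S, T)."""
    return stack.events.sum(axis=1)


def viewing_synchrony(
    stack: ViewingStack,
    null_fractions: np.ndarray,
    q: float = 0.05,
) -> FrameClassification:
    """Per-frame fraction of viewings with events, tested against a rest null.

    Reuses the group synchrony machinery with (subject, viewing) segments as
    the exchangeable units.
    """
    S, V, T = stack.events.shape
    flat = stack.events.reshape(S * V, T)
    ids = [f"{stack.subject_ids[s]}_v{v}" for s in range(S) for v in range(V)]
    return synchrony_test(GroupEventMatrix(data=flat, subject_ids=ids), null_fractions, q=q)


def frame_similarity(stack: ViewingStack) -> np.ndarray:
    """Mean pairwise Pearson similarity of co-fluctuation patterns per frame.

    At each clip frame, the patterns of all (subject, viewing) units are
    correlated pairwise and averaged.
    """
    if stack.edges is None:
        raise ValueError("frame_similarity requires edge series in the stack")
    units = [e for row in stack.edges for e in row]
    T = stack.n_frames
    n = len(units)
    out = np.empty(T)
    iu = np.triu_indices(n, k=1)
    for t in range(T):
        P = np.vstack([u.data[t] for u in units])
        C = np.corrcoef(P)
        out[t] = float(C[iu].mean())
    return out


def synchrony_similarity_relation(
    fractions: np.ndarray,
    similarities: np.ndarray,
    mean_rss: np.ndarray | None = None,
) -> dict[str, tuple[float, float]]:
    """Correlate per-frame event synchrony (and optionally amplitude) with
    per-frame pattern similarity.  Returns {name: (r, p)}."""
    fractions = np.asarray(fractions, dtype=float)
    similarities = np.asarray(similarities, dtype=float)
    if fractions.shape != similarities.shape:
        raise ValueError("inputs must have equal length")
    out = {}
    r, p = stats.pearsonr(fractions, similarities)
    out["fraction_vs_similarity"] = (float(r), float(p))
    if mean_rss is not None:
        r2, p2 = stats.pearsonr(np.asarray(mean_rss, dtype=float), similarities)
        out["rss_vs_similarity"] = (float(r2), float(p2))
    return out


def select_peaks(
    fractions: np.ndarray,
    significant: np.ndarray | None = None,
    prominence: float = 0.1,
) -> np.ndarray:
    """Local maxima of the synchrony fraction series, optionally restricted
    to significant frames.  Manual peak lists can be passed straight to
    ``peak_pattern_discrimination`` instead."""
    series = np.asarray(fractions, dtype=float)
    peaks, _ = find_peaks(series, prominence=prominence)
    if significant is not None:
        peaks = peaks[np.asarray(significant, dtype=bool)[peaks]]
    return peaks


def peak_pattern_discrimination(
    stack: ViewingStack,
    peak_frames: Sequence[int],
) -> tuple[float, float, float, float]:
    """Is each synchrony peak's pattern more similar to itself than to others?

    All (subject, viewing) instantiations of each peak frame are correlated
    pairwise; same-peak similarities are compared against cross-peak
    similarities with a Welch test.  Returns (t, p, mean_within,
    mean_between).  Peaks with fewer than 2 instantiations are skipped.
    """
    if stack.edges is None:
        raise ValueError("pattern discrimination requires edge series")
    peak_frames = [int(f) for f in peak_frames]
    if len(peak_frames) < 2:
        raise ValueError("need at least 2 peaks")
    units = [e for row in stack.edges for e in row]
    vectors, labels = [], []
    for f in peak_frames:
        for u in units:
            vectors.append(u.data[f])
            labels.append(f)
    P = np.vstack(vectors)
    C = np.corrcoef(P)
    labels_arr = np.asarray(labels)
    iu = np.triu_indices(len(labels), k=1)
    same = labels_arr[iu[0]] == labels_arr[iu[1]]
    within = C[iu][same]
    between = C[iu][~same]
    if within.size < 2 or between.size < 2:
        raise ValueError("not enough similarity pairs for the test")
    res = stats.ttest_ind(within, between, equal_var=False)
    return float(res.statistic), float(res.pvalue), float(within.mean()), float(between.mean())
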