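"""Event-type comparisons: amplitude, pattern similarity, mean patterns,
peak-locked temporal profiles, and edge-wise difference concordance.

Each detected event carries a whole-brain co-fluctuation pattern — the frame
of the edge time series at its peak, equivalently the rank-1 (up to sign)
matrix z(t) z(t)^T with zero diagonal.  Events of the three classes
(boundary / movie / asynchronous) are compared on amplitude, on pairwise
pattern similarity aggregated into a (3 * n_subjects) square block matrix,
and on their edge-wise and temporal structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from ._spatial import spatial_permutations
from .edgets import EdgeSeries, RSSSeries
from .synchrony import EVENT_CLASSES

__all__ = [
    "CoFluctuationPattern",
    "TypedSimilarityMatrix",
    "event_patterns",
    "amplitude_by_type",
    "global_similarity",
    "within_vs_between",
    "mean_pattern",
    "peak_locked_profiles",
    "pattern_differences",
]


@dataclass
class CoFluctuationPattern:
    """One event's co-fluctuation pattern (canonical edge-index vectorization)."""

    vector: np.ndarray
    subject: str
    frame: int
    label: str
    scan: str = "movie"

    def matrix(self) -> np.ndarray:
        """Symmetric N x N form with zero diagonal."""
        return squareform(self.vector, checks=False)


@dataclass
class TypedSimilarityMatrix:
    """(3S) x (3S) mean pairwise event-pattern similarity.

    Rows/columns are ordered type-major: all subjects of the first type,
    then the second, then the third.  Cell ((a, r), (b, s)) averages the
    similarity between subject r's type-a events and subject s's type-b
    events; per-pair aggregation is asymmetric by construction and is stored
    as computed.  Cells with no event pair are NaN.
    """

    matrix: np.ndarray
    subjects: list[str]
    types: tuple[str, ...] = EVENT_CLASSES
    block_order: list[tuple[str, str]] = field(default_factory=list)


def event_patterns(
    edges: EdgeSeries,
    labeled_events: Sequence[tuple[int, str]],
    subject: str = "sub000",
    scan: str = "movie",
) -> list[CoFluctuationPattern]:
    """One pattern per labeled event peak: the peak frame's edge-series row."""
    out = []
    for frame, label in labeled_events:
        if not 0 <= frame < edges.n_frames:
            raise IndexError(f"event frame {frame} outside scan of {edges.n_frames} frames")
        out.append(
            CoFluctuationPattern(
                vector=edges.data[frame].copy(), subject=subject, frame=int(frame), label=label, scan=scan
            )
        )
    return out


def amplitude_by_type(
    rss_series: RSSSeries | Mapping[str, RSSSeries],
    labeled_events: Sequence[tuple[int, str]] | Sequence[tuple[str, int, str]],
) -> tuple[dict[str, np.ndarray], dict[tuple[str, str], tuple[float, float]]]:
    """RSS amplitudes grouped by event type, with Welch tests per type pair.

    Accepts either one scan's RSS with (frame, label) events, or a mapping
    of scan key -> RSS with (scan, frame, label) events.  Pairs where a type
    has fewer than 2 events are skipped with a warning.
    """
    values: dict[str, list[float]] = {t: [] for t in EVENT_CLASSES}
    if isinstance(rss_series, RSSSeries):
        for frame, label in labeled_events:  # type: ignore[misc]
            values.setdefault(label, []).append(float(rss_series.data[frame]))
    else:
        for scan, frame, label in labeled_events:  # type: ignore[misc]
            values.setdefault(label, []).append(float(rss_series[scan].data[frame]))
    arrays = {t: np.asarray(v) for t, v in values.items()}
    tests: dict[tuple[str, str], tuple[float, float]] = {}
    types = [t for t in arrays]
    for i, a in enumerate(types):
        for b in types[i + 1 :]:
            if arrays[a].size < 2 or arrays[b].size < 2:
                warnings.warn(f"skipping amplitude test {a} vs {b}: fewer than 2 events in a type")
                continue
            res = stats.ttest_ind(arrays[a], arrays[b], equal_var=False)
            tests[(a, b)] = (float(res.statistic), float(res.pvalue))
    return arrays, tests


def _similarity_matrix(P: np.ndarray, metric: str) -> np.ndarray:
    """Pairwise similarity of pattern rows under the chosen metric."""
    if metric == "pearson":
        return np.corrcoef(P)
    if metric == "spearman":
        ranks = np.apply_along_axis(stats.rankdata, 1, P)
        return np.corrcoef(ranks)
    if metric == "nmi":
        return _nmi_matrix(P)
    raise ValueError(f"unknown similarity metric: {metric}")


def _nmi_matrix(P: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Normalized mutual information between decile-binned pattern vectors."""
    n = P.shape[0]
    binned = np.empty_like(P, dtype=int)
    for i in range(n):
        edges = np.quantile(P[i], np.linspace(0, 1, n_bins + 1)[1:-1])
        binned[i] = np.searchsorted(edges, P[i])

    def entropy(counts: np.ndarray) -> float:
        p = counts[counts > 0] / counts.sum()
        return float(-(p * np.log(p)).sum())

    out = np.eye(n)
    for i in range(n):
        hi = entropy(np.bincount(binned[i], minlength=n_bins).astype(float))
        for j in range(i + 1, n):
            hj = entropy(np.bincount(binned[j], minlength=n_bins).astype(float))
            joint = np.histogram2d(binned[i], binned[j], bins=n_bins)[0]
            hij = entropy(joint.ravel())
            mi = hi + hj - hij
            denom = np.sqrt(hi * hj)
            out[i, j] = out[j, i] = mi / denom if denom > 0 else 0.0
    return out


def global_similarity(
    patterns: Iterable[CoFluctuationPattern],
    metric: str = "pearson",
    subjects: Sequence[str] | None = None,
) -> TypedSimilarityMatrix:
    """Mean pairwise event similarity aggregated by (type, subject) blocks.

    For every pair of subjects the full event-by-event similarity matrix is
    averaged within each (type, type) cell, producing a 3 x 3 summary per
    pair; assembled over all pairs this yields the (3S) x (3S) matrix (387
    square for 129 subjects).  Same-subject same-type cells average distinct
    event pairs only; NaN marks cells with no contributing pair.
    """
    patterns = list(patterns)
    if not patterns:
        raise ValueError("no patterns given")
    if subjects is None:
        subjects = sorted({p.subject for p in patterns})
    subjects = list(subjects)
    sub_idx = {s: i for i, s in enumerate(subjects)}
    type_idx = {t: i for i, t in enumerate(EVENT_CLASSES)}

    P = np.vstack([p.vector for p in patterns])
    sim = _similarity_matrix(P, metric)
    groups = np.array([type_idx[p.label] * len(subjects) + sub_idx[p.subject] for p in patterns])

    S = len(subjects)
    n_cells = 3 * S
    sums = np.zeros((n_cells, n_cells))
    counts = np.zeros((n_cells, n_cells))
    np.add.at(sums, (groups[:, None], groups[None, :]), sim)
    np.add.at(counts, (groups[:, None], groups[None, :]), 1.0)
    # same-event self pairs inflate the diagonal cells: remove them
    np.subtract.at(sums, (groups, groups), 1.0)
    np.subtract.at(counts, (groups, groups), 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        matrix = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    block_order = [(t, s) for t in EVENT_CLASSES for s in subjects]
    return TypedSimilarityMatrix(matrix=matrix, subjects=subjects, block_order=block_order)


def within_vs_between(sim: TypedSimilarityMatrix, event_type: str) -> tuple[float, float, float, float]:
    """Welch test: within-type block similarity vs between-type blocks.

    The stored matrix contains each unique (subject pair, type pair) mean
    twice — cell ((a, r), (b, s)) equals ((b, s), (a, r)) — so only one copy
    of each is used: the upper triangle (plus diagonal) of the within-type
    block, and one orientation of each cross-type block.  Returns
    (t, p, mean_within, mean_between).
    """
    S = len(sim.subjects)
    if S < 2:
        raise ValueError("need at least 2 subjects")
    a = sim.types.index(event_type)
    blocks = {
        (i, j): sim.matrix[i * S : (i + 1) * S, j * S : (j + 1) * S]
        for i in range(3)
        for j in range(3)
    }
    iu = np.triu_indices(S)
    within = blocks[(a, a)][iu]
    between = np.concatenate([blocks[(a, j)].ravel() for j in range(3) if j != a])
    within = within[~np.isnan(within)]
    between = between[~np.isnan(between)]
    if within.size < 2 or between.size < 2:
        raise ValueError("too few finite similarity values for the test")
    res = stats.ttest_ind(within, between, equal_var=False)
    return float(res.statistic), float(res.pvalue), float(within.mean()), float(between.mean())


@dataclass
class SystemBlockResult:
    """System-by-system block means of a mean pattern, with permutation p's."""

    mean_vector: np.ndarray
    block_means: np.ndarray
    block_p: np.ndarray
    block_q_sig: np.ndarray
    systems: list[str]

    def top_block(self, between_only: bool = False) -> tuple[str, str]:
        """The significant block with the largest |mean|.

        ``between_only`` restricts the search to between-system blocks,
        where planted (or stimulus-driven) cross-system signatures live —
        within-system blocks are elevated by background modularity
        regardless of events.  Falls back to the largest overall block if
        nothing passes FDR.
        """
        mask = self.block_q_sig if self.block_q_sig.any() else np.ones_like(self.block_q_sig, bool)
        if between_only:
            mask = mask & ~np.eye(len(self.systems), dtype=bool)
        masked = np.where(mask, np.abs(self.block_means), -np.inf)
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        return self.systems[min(i, j)], self.systems[max(i, j)]


def _block_means(M: np.ndarray, sys_of_node: np.ndarray, n_systems: int) -> np.ndarray:
    """Mean edge value within each (system, system) block, excluding the diagonal."""
    out = np.zeros((n_systems, n_systems))
    ind = [np.flatnonzero(sys_of_node == k) for k in range(n_systems)]
    for a in range(n_systems):
        for b in range(a, n_systems):
            sub = M[np.ix_(ind[a], ind[b])]
            if a == b:
                n = sub.shape[0]
                total, cnt = sub.sum(), n * n - n
                val = total / cnt if cnt else np.nan
            else:
                val = sub.mean()
            out[a, b] = out[b, a] = val
    return out


def mean_pattern(
    patterns: Sequence[CoFluctuationPattern],
    system_labels: Sequence[str],
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
    centroids: np.ndarray | None = None,
    q: float = 0.05,
) -> SystemBlockResult:
    """Element-wise mean pattern of one event type with system-block tests.

    Block significance uses a node-permutation null — a spin test when
    parcel centroids are supplied, otherwise size-preserving label
    shuffles — with two-sided p-values, BH-FDR across blocks.
    """
    if not patterns:
        raise ValueError("mean_pattern requires at least one pattern")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mean_vec = np.mean([p.vector for p in patterns], axis=0)
    M = squareform(mean_vec, checks=False)
    systems = list(dict.fromkeys(system_labels))
    sys_of_node = np.array([systems.index(s) for s in system_labels])
    K = len(systems)
    observed = _block_means(M, sys_of_node, K)

    perms = spatial_permutations(len(system_labels), n_perm, rng, centroids)
    null = np.empty((n_perm, K, K))
    for k in range(n_perm):
        # permute the node identity of the map, keeping system geometry fixed
        Mp = M[np.ix_(perms[k], perms[k])]
        null[k] = _block_means(Mp, sys_of_node, K)
    center = null.mean(axis=0)
    n_ge = np.sum(np.abs(null - center) >= np.abs(observed - center)[None], axis=0)
    p_full = (1.0 + n_ge) / (1.0 + n_perm)
    iu = np.triu_indices(K)
    rej = multipletests(p_full[iu], alpha=q, method="fdr_bh")[0]
    q_sig = np.zeros((K, K), dtype=bool)
    q_sig[iu] = rej
    q_sig = q_sig | q_sig.T
    return SystemBlockResult(
        mean_vector=mean_vec, block_means=observed, block_p=p_full, block_q_sig=q_sig, systems=systems
    )


@dataclass
class PeakLockedProfiles:
    """Mean RSS around event peaks per type, with per-offset pairwise tests."""

    offsets: np.ndarray
    profiles: dict[str, np.ndarray]
    counts: dict[str, np.ndarray]
    pairwise_p: dict[tuple[str, str], np.ndarray]
    bonferroni_m: int


def peak_locked_profiles(
    rss_by_scan: Mapping[str, RSSSeries],
    labeled_events: Sequence[tuple[str, int, str]],
    half_window: int = 10,
) -> PeakLockedProfiles:
    """Align every event to its peak and average RSS per type per offset.

    Events closer than ``half_window`` to a scan edge contribute a
    NaN-masked slice.  Per-offset Welch tests between type pairs are
    Bonferroni-corrected for the 2*half_window + 1 offsets.
    """
    offsets = np.arange(-half_window, half_window + 1)
    slices: dict[str, list[np.ndarray]] = {t: [] for t in EVENT_CLASSES}
    for scan, frame, label in labeled_events:
        trace = rss_by_scan[scan].data
        T = trace.shape[0]
        sl = np.full(offsets.shape[0], np.nan)
        lo, hi = max(0, frame - half_window), min(T, frame + half_window + 1)
        sl[(lo - frame) + half_window : (hi - frame) + half_window] = trace[lo:hi]
        slices.setdefault(label, []).append(sl)
    profiles, counts = {}, {}
    stacked: dict[str, np.ndarray] = {}
    for t, rows in slices.items():
        if rows:
            A = np.vstack(rows)
            stacked[t] = A
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                profiles[t] = np.nanmean(A, axis=0)
            counts[t] = np.sum(~np.isnan(A), axis=0)
        else:
            profiles[t] = np.full(offsets.shape[0], np.nan)
            counts[t] = np.zeros(offsets.shape[0], dtype=int)
    m = offsets.shape[0]
    pairwise_p: dict[tuple[str, str], np.ndarray] = {}
    names = list(stacked)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            p = np.full(m, np.nan)
            for k in range(m):
                xa = stacked[a][:, k]
                xb = stacked[b][:, k]
                xa, xb = xa[~np.isnan(xa)], xb[~np.isnan(xb)]
                if xa.size >= 2 and xb.size >= 2:
                    p[k] = stats.ttest_ind(xa, xb, equal_var=False).pvalue
            pairwise_p[(a, b)] = np.minimum(p * m, 1.0)
    return PeakLockedProfiles(
        offsets=offsets, profiles=profiles, counts=counts, pairwise_p=pairwise_p, bonferroni_m=m
    )


@dataclass
class EdgeDifferenceResult:
    """Per-edge signed differences between two event types across subjects."""

    signs: np.ndarray  # (n_subjects, E) in {-1, 0, +1}
    t_values: np.ndarray
    p_values: np.ndarray
    q_sig: np.ndarray
    sign_consensus: np.ndarray
    subjects: list[str]


def pattern_differences(
    patterns: Iterable[CoFluctuationPattern],
    type_pair: tuple[str, str],
    q: float = 0.05,
) -> EdgeDifferenceResult:
    """Within-subject edge-wise difference signs plus a group paired test.

    For each subject with events of both types, the per-edge difference of
    mean co-fluctuation (type A minus type B) is reduced to its sign; across
    subjects each edge gets a paired t-test on the per-subject means,
    BH-FDR-corrected across edges.  Subjects missing a type are excluded
    with a warning; at least 2 complete subjects are required.
    """
    a, b = type_pair
    by_subject: dict[str, dict[str, list[np.ndarray]]] = {}
    for p in patterns:
        by_subject.setdefault(p.subject, {}).setdefault(p.label, []).append(p.vector)
    means_a, means_b, kept = [], [], []
    for s, d in sorted(by_subject.items()):
        if a in d and b in d:
            means_a.append(np.mean(d[a], axis=0))
            means_b.append(np.mean(d[b], axis=0))
            kept.append(s)
        else:
            warnings.warn(f"subject {s} lacks events of type {a if a not in d else b}; excluded")
    if len(kept) < 2:
        raise ValueError("paired group test requires at least 2 subjects with both types")
    A = np.vstack(means_a)
    B = np.vstack(means_b)
    signs = np.sign(A - B).astype(int)
    res = stats.ttest_rel(A, B, axis=0)
    t_vals = np.asarray(res.statistic, dtype=float)
    p_vals = np.asarray(res.pvalue, dtype=float)
    p_for_bh = np.where(np.isnan(p_vals), 1.0, p_vals)
    q_sig = multipletests(p_for_bh, alpha=q, method="fdr_bh")[0]
    return EdgeDifferenceResult(
        signs=signs,
        t_values=t_vals,
        p_values=p_vals,
        q_sig=q_sig,
        sign_consensus=signs.mean(axis=0),
        subjects=kept,
    )
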