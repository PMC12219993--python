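"""Synthetic multi-subject movie and rest BOLD with planted event structure.

The generator emulates the ingredients the downstream pipeline is built to
detect, at the level of their statistical signatures rather than biophysics:

* a modular background — each node mixes a per-system latent Gaussian
  signal with private noise, ``x = sqrt(c) * latent(system) +
  sqrt(1 - c) * private``, yielding block-structured functional
  connectivity with within-system coupling ``c``;
* shared, HRF-convolved responses at coded scene-ending frames, with a
  signed activation pattern (visual deactivation, control/salience
  activation) scaled by ``boundary_gain``;
* a second shared response pattern injected at mid-movie frames
  (``movie_gain``);
* subject-private bursts at Poisson-random frames with individually drawn
  random patterns (``async_gain``), present in movie and rest alike;
* white measurement noise.

Rest scans contain only background, private bursts, and noise.  The ground
truth of every planted frame and its class is returned alongside the scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .boundaries import canonical_hrf
from .edgets import ParcelTimeSeries

__all__ = ["SimSpec", "SimOutput", "simulate_group", "simulate_viewings", "default_activation_pattern"]

_SYSTEM_NAMES = ["visual", "control", "salience", "default_mode", "dorsal_attention", "somatomotor"]

# asynchronous bursts are kept this many seconds away from shared frames so
# that planted classes stay temporally unambiguous
_ASYNC_GUARD_SECONDS = 15.0


@dataclass
class SimSpec:
    """Study-design parameters for one simulated group.

    Defaults describe a mid-sized naturalistic session: 20 subjects, one
    10-minute movie scan and one rest scan each at TR = 1 s, 60 nodes in 6
    systems, 4 coded scene endings and 3 shared mid-movie responses, and
    about 3 private bursts per scan.
    """

    n_subjects: int = 20
    n_nodes: int = 60
    n_systems: int = 6
    n_frames: int = 600
    tr_seconds: float = 1.0
    boundary_frames: tuple[int, ...] = (100, 220, 340, 460)
    movie_event_frames: tuple[int, ...] = (160, 280, 400)
    boundary_gain: float = 5.0
    movie_gain: float = 4.0
    async_rate: float = 3.0
    async_gain: float = 4.0
    noise_sd: float = 1.0
    system_coupling: float = 0.3
    activation_pattern: np.ndarray | None = None
    jitter_frames: int = 1
    n_rest_scans: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_nodes < 2 or self.n_systems < 1:
            raise ValueError("need at least 1 subject, 2 nodes, 1 system")
        if not 0 <= self.system_coupling < 1:
            raise ValueError("system_coupling must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if min(self.boundary_gain, self.movie_gain, self.async_gain, self.async_rate) < 0:
            raise ValueError("gains and rates must be non-negative")
        b = np.asarray(self.boundary_frames, dtype=int)
        m = np.asarray(self.movie_event_frames, dtype=int)
        allf = np.concatenate([b, m])
        if allf.size and (allf.min() < 0 or allf.max() >= self.n_frames):
            raise ValueError("planted frames must lie in [0, n_frames)")
        if np.intersect1d(b, m).size:
            raise ValueError("boundary and movie event frames must be disjoint")
        if self.n_frames * self.tr_seconds < 32.0:
            raise ValueError("scan too short for the 32 s HRF kernel")

    @property
    def system_sizes(self) -> list[int]:
        return [len(g) for g in np.array_split(np.arange(self.n_nodes), self.n_systems)]


@dataclass
class SimOutput:
    """Simulated scans plus the planted ground truth."""

    movie_scans: list[ParcelTimeSeries]
    rest_scans: list[ParcelTimeSeries]
    truth: pd.DataFrame  # columns: subject, condition, frame, label
    spec: SimSpec
    boundary_frames: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    activation_pattern: np.ndarray | None = None
    movie_pattern: np.ndarray | None = None
    centroids: np.ndarray | None = None


def _system_labels(spec: SimSpec) -> list[str]:
    names = [
        _SYSTEM_NAMES[k] if k < len(_SYSTEM_NAMES) else f"system{k}"
        for k in range(spec.n_systems)
    ]
    labels: list[str] = []
    for k, group in enumerate(np.array_split(np.arange(spec.n_nodes), spec.n_systems)):
        labels.extend([names[k]] * len(group))
    return labels


def default_activation_pattern(spec: SimSpec) -> np.ndarray:
    """Signed boundary-response loadings: visual deactivation, control and
    salience activation, zero elsewhere.

    Magnitudes are graded (visual 1.2, control 1.0, salience 0.6) so the
    cross-system co-fluctuation blocks of the rank-1 planted pattern have
    strictly ordered strengths, the visual-control interaction strongest.
    """
    labels = _system_labels(spec)
    pattern = np.zeros(spec.n_nodes)
    for i, lab in enumerate(labels):
        if lab == "visual":
            pattern[i] = -1.2
        elif lab == "control":
            pattern[i] = 1.0
        elif lab == "salience":
            pattern[i] = 0.6
    if not np.any(pattern):  # fewer than 2 named systems: alternate signs
        pattern = np.where(np.arange(spec.n_nodes) % 2 == 0, 1.0, -1.0)
    return pattern


def _unit_rms(v: np.ndarray) -> np.ndarray:
    return v / np.sqrt(np.mean(v**2))


def _injection(frames: np.ndarray, pattern: np.ndarray, gain: float, T: int, kernel: np.ndarray) -> np.ndarray:
    """HRF-convolved impulses at ``frames`` times an outer spatial pattern."""
    if frames.size == 0 or gain == 0:
        return np.zeros((T, pattern.shape[0]))
    impulses = np.zeros(T)
    impulses[frames] = 1.0
    reg = np.convolve(impulses, kernel)[:T]
    return gain * np.outer(reg, pattern)


def _jittered(frames: np.ndarray, rng: np.random.Generator, jitter: int, T: int) -> np.ndarray:
    if jitter == 0 or frames.size == 0:
        return frames
    out = frames + rng.integers(-jitter, jitter + 1, size=frames.size)
    return np.clip(out, 0, T - 1)


def _async_frames(rng: np.random.Generator, spec: SimSpec, forbidden: np.ndarray) -> np.ndarray:
    n = rng.poisson(spec.async_rate)
    if n == 0:
        return np.array([], dtype=int)
    guard = int(round(_ASYNC_GUARD_SECONDS / spec.tr_seconds))
    allowed = np.ones(spec.n_frames, dtype=bool)
    for f in forbidden:
        allowed[max(0, f - guard) : f + guard + 1] = False
    pool = np.flatnonzero(allowed)
    if pool.size == 0:
        return np.array([], dtype=int)
    return np.sort(rng.choice(pool, size=min(n, pool.size), replace=False))


def _background(rng: np.random.Generator, spec: SimSpec, sys_of_node: np.ndarray) -> np.ndarray:
    c = spec.system_coupling
    latents = rng.standard_normal((spec.n_frames, spec.n_systems))
    private = rng.standard_normal((spec.n_frames, spec.n_nodes))
    return np.sqrt(c) * latents[:, sys_of_node] + np.sqrt(1.0 - c) * private


def simulate_group(spec: SimSpec, n_viewings: int = 1) -> SimOutput | list[SimOutput]:
    """Simulate one group (or several aligned viewings) of movie + rest scans.

    With ``n_viewings > 1`` the group-shared ingredients (activation and
    movie patterns, planted frames, parcel centroids) are held fixed while
    background, jitter, bursts and noise are redrawn, emulating repeated
    presentations of the same clip; a list of per-viewing outputs is
    returned.
    """
    root = np.random.SeedSequence(spec.seed)
    group_rng = np.random.default_rng(root.spawn(1)[0])

    sys_groups = np.array_split(np.arange(spec.n_nodes), spec.n_systems)
    sys_of_node = np.empty(spec.n_nodes, dtype=int)
    for k, g in enumerate(sys_groups):
        sys_of_node[g] = k
    system_labels = _system_labels(spec)
    node_labels = [f"node{i:03d}" for i in range(spec.n_nodes)]

    act = spec.activation_pattern
    act = default_activation_pattern(spec) if act is None else np.asarray(act, dtype=float)
    if act.shape[0] != spec.n_nodes:
        raise ValueError("activation_pattern length must equal n_nodes")
    movie_pattern = _unit_rms(group_rng.standard_normal(spec.n_nodes))
    centroids = group_rng.standard_normal((spec.n_nodes, 3))
    centroids /= np.linalg.norm(centroids, axis=1, keepdims=True)

    kernel = canonical_hrf(spec.tr_seconds)
    b_frames = np.asarray(spec.boundary_frames, dtype=int)
    m_frames = np.asarray(spec.movie_event_frames, dtype=int)
    shared = np.concatenate([b_frames, m_frames])

    outputs = []
    for viewing in range(n_viewings):
        movie_scans, rest_scans, truth_rows = [], [], []
        for s in range(spec.n_subjects):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=spec.seed, spawn_key=(1, s, viewing))
            )
            # movie scan
            X = _background(rng, spec, sys_of_node)
            bj = _jittered(b_frames, rng, spec.jitter_frames, spec.n_frames)
            mj = _jittered(m_frames, rng, spec.jitter_frames, spec.n_frames)
            X += _injection(bj, act, spec.boundary_gain, spec.n_frames, kernel)
            X += _injection(mj, movie_pattern, spec.movie_gain, spec.n_frames, kernel)
            a_movie = _async_frames(rng, spec, shared)
            for f in a_movie:
                pat = _unit_rms(rng.standard_normal(spec.n_nodes))
                X += _injection(np.array([f]), pat, spec.async_gain, spec.n_frames, kernel)
            X += spec.noise_sd * rng.standard_normal(X.shape)
            movie_scans.append(
                ParcelTimeSeries(X, spec.tr_seconds, node_labels, system_labels, centroids)
            )
            # rest scans: background + private bursts only.  Several rest
            # sessions per subject keep the pooled null fine-grained enough
            # for FDR control over the movie frames.
            rest_async: list[np.ndarray] = []
            for _ in range(spec.n_rest_scans):
                R = _background(rng, spec, sys_of_node)
                a_rest = _async_frames(rng, spec, np.array([], dtype=int))
                for f in a_rest:
                    pat = _unit_rms(rng.standard_normal(spec.n_nodes))
                    R += _injection(np.array([f]), pat, spec.async_gain, spec.n_frames, kernel)
                R += spec.noise_sd * rng.standard_normal(R.shape)
                rest_scans.append(
                    ParcelTimeSeries(R, spec.tr_seconds, node_labels, system_labels, centroids)
                )
                rest_async.append(a_rest)

            for f in b_frames:
                truth_rows.append((s, "movie", int(f), "boundary"))
            for f in m_frames:
                truth_rows.append((s, "movie", int(f), "movie"))
            for f in a_movie:
                truth_rows.append((s, "movie", int(f), "asynchronous"))
            for frames in rest_async:
                for f in frames:
                    truth_rows.append((s, "rest", int(f), "asynchronous"))

        truth = pd.DataFrame(truth_rows, columns=["subject", "condition", "frame", "label"])
        outputs.append(
            SimOutput(
                movie_scans=movie_scans,
                rest_scans=rest_scans,
                truth=truth,
                spec=spec,
                boundary_frames=b_frames,
                activation_pattern=act,
                movie_pattern=movie_pattern,
                centroids=centroids,
            )
        )
    return outputs[0] if n_viewings == 1 else outputs


def simulate_viewings(spec: SimSpec, n_viewings: int) -> list[SimOutput]:
    """Repeated presentations of the same clip (see ``simulate_group``)."""
    if n_viewings < 2:
        raise ValueError("need at least 2 viewings")
    return simulate_group(spec, n_viewings=n_viewings)
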