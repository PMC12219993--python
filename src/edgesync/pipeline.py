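"""End-to-end orchestration: scans in, classified events and summaries out.

``run_pipeline`` chains every stage — z-scoring, edge decomposition, RSS,
event detection, group synchrony against the rest null, tripartite
classification, event characterization, and boundary activation analysis —
writing each result as delimited text with a log of the seed and all
thresholds.  All randomness is derived from the single configured seed via
per-stage child seeds, so identical inputs give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import io as esio
from .activation import ActivationMap, activation_map, boundary_indicator, stability_test, system_test
from .boundaries import (
    BoundaryAnnotation,
    LagProfile,
    convolve_boundaries,
    lagged_correlation,
    peri_boundary_profile,
    windowed_shift_test,
)
from .characterize import (
    CoFluctuationPattern,
    EdgeDifferenceResult,
    PeakLockedProfiles,
    SystemBlockResult,
    TypedSimilarityMatrix,
    amplitude_by_type,
    event_patterns,
    global_similarity,
    mean_pattern,
    pattern_differences,
    peak_locked_profiles,
    within_vs_between,
)
from .edgets import ParcelTimeSeries, RSSSeries, edge_time_series, rss, zscore
from .events import EventSeries, detect_events, null_rss
from .io import RunConfig, stage_seed
from .synchrony import (
    BOUNDARY,
    MOVIE,
    FrameClassification,
    classify_frames,
    label_subject_events,
    rest_null_fractions,
    shift_null_fractions,
    stack_events,
    synchrony_test,
)

__all__ = ["PipelineResult", "run_pipeline", "detect_scan_events"]


@dataclass
class PipelineResult:
    """Everything the pipeline computed, for downstream use and inspection."""

    config: RunConfig
    boundary: BoundaryAnnotation
    movie_events: list[EventSeries]
    rest_events: list[EventSeries]
    movie_rss: list[RSSSeries]
    rest_rss: list[RSSSeries]
    classification: FrameClassification
    lag_profile: LagProfile
    peri_event_profile: LagProfile
    peri_rss_profile: LagProfile
    shift_test_p: float
    labeled_events: list[list[tuple[int, str]]]
    patterns: list[CoFluctuationPattern]
    amplitudes: dict[str, np.ndarray]
    amplitude_tests: dict[tuple[str, str], tuple[float, float]]
    similarity: TypedSimilarityMatrix | None
    within_between: dict[str, tuple[float, float, float, float]]
    boundary_pattern: SystemBlockResult | None
    peak_profiles: PeakLockedProfiles
    differences: EdgeDifferenceResult | None
    activation_maps: list[ActivationMap]
    system_p: dict[str, float]
    stability: tuple[float, float]
    subject_ids: list[str] = field(default_factory=list)


def detect_scan_events(
    ts: ParcelTimeSeries,
    alpha: float,
    n_null: int,
    seed: int,
) -> tuple[EventSeries, RSSSeries]:
    """Z-score, build the circular-shift null, and detect one scan's events."""
    zts = zscore(ts)
    edges = edge_time_series(zts, assume_zscored=True)
    rss_series = rss(edges)
    null = null_rss(zts, n_null=n_null, seed=seed, alpha=alpha)
    return detect_events(rss_series, null), rss_series


def _load_scans(entries: Sequence, tr: float, systems: Mapping[str, str] | None, centroids) -> list[ParcelTimeSeries]:
    scans = []
    for e in entries:
        if isinstance(e, ParcelTimeSeries):
            scans.append(e)
        else:
            ts = esio.read_parcel_timeseries(e, tr, centroids=centroids)
            if systems:
                ts.system_labels = [systems.get(str(n), "unassigned") for n in ts.node_labels]
            scans.append(ts)
    return scans


def run_pipeline(
    config: RunConfig,
    manifest: Mapping[str, object],
    out_dir: str | Path | None = None,
    null_mode: str = "rest",
) -> PipelineResult:
    """Run every stage on a group of movie and rest scans.

    ``manifest`` maps ``movie`` and ``rest`` to lists of scan paths (or
    in-memory ``ParcelTimeSeries``), ``boundaries`` to a coded-endings file
    (or a frame array), and optionally ``systems``/``centroids``.
    ``null_mode='shift'`` replaces the rest-based synchrony null with the
    circular-shift null as a sensitivity analysis.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    systems = manifest.get("systems")
    if systems is not None and not isinstance(systems, Mapping):
        systems = esio.read_systems(systems)  # type: ignore[arg-type]
    centroids = manifest.get("centroids")

    movie_scans = _load_scans(manifest.get("movie", []), config.tr_seconds, systems, centroids)
    rest_scans = _load_scans(manifest.get("rest", []), config.tr_seconds, systems, centroids)
    if not movie_scans:
        raise ValueError("manifest contains no movie scans")
    if not rest_scans and null_mode == "rest":
        raise ValueError(
            "the rest-based synchrony null requires at least one rest scan; "
            "provide rest scans or use null_mode='shift'"
        )
    shapes = {s.data.shape for s in movie_scans + rest_scans}
    if len(shapes) != 1:
        raise ValueError(f"all scans in a group must share T and N; got {sorted(shapes)}")
    T, N = movie_scans[0].data.shape
    subject_ids = [f"sub{i:03d}" for i in range(len(movie_scans))]

    bspec = manifest.get("boundaries")
    if isinstance(bspec, BoundaryAnnotation):
        boundary = bspec
    elif isinstance(bspec, (str, Path)):
        boundary = esio.read_boundaries(bspec, config.tr_seconds, T)
    elif bspec is not None:
        boundary = convolve_boundaries(np.asarray(bspec, dtype=int), T, config.tr_seconds)
    else:
        raise ValueError("manifest must provide boundaries (path, frames, or annotation)")

    # --- per-scan event detection -------------------------------------------------
    movie_events, movie_rss = [], []
    for i, ts in enumerate(movie_scans):
        ev, rs = detect_scan_events(
            ts, config.event_alpha, config.n_null, stage_seed(config.seed, f"events/movie/{i}")
        )
        movie_events.append(ev)
        movie_rss.append(rs)
    rest_events, rest_rss = [], []
    for i, ts in enumerate(rest_scans):
        ev, rs = detect_scan_events(
            ts, config.event_alpha, config.n_null, stage_seed(config.seed, f"events/rest/{i}")
        )
        rest_events.append(ev)
        rest_rss.append(rs)

    # --- group synchrony and tripartite classification ---------------------------
    movie_group = stack_events(movie_events, subject_ids)
    if null_mode == "rest":
        # pool rest sessions: each group of up to S independent rest scans
        # yields one per-frame fraction series for the null
        S = len(movie_scans)
        groups = [
            stack_events(rest_events[i : i + S])
            for i in range(0, len(rest_events) - S + 1, S)
        ] or [stack_events(rest_events)]
        null_fracs = rest_null_fractions(groups)
    elif null_mode == "shift":
        null_fracs = shift_null_fractions(
            movie_group, n_shifts=config.n_null,
            seed=np.random.default_rng(stage_seed(config.seed, "shift_null")),
        )
    else:
        raise ValueError("null_mode must be 'rest' or 'shift'")
    classification = synchrony_test(movie_group, null_fracs, q=config.fdr_q)
    classification = classify_frames(classification, boundary, config.boundary_window_seconds)

    # --- lag analyses -------------------------------------------------------------
    group_fraction = movie_group.data.mean(axis=0)
    impulses = np.zeros(T)
    impulses[boundary.ending_frames] = 1.0
    lag_profile = lagged_correlation(
        impulses, group_fraction, config.lag_range_seconds, config.tr_seconds
    )
    peri_event = peri_boundary_profile(
        [e.frames for e in movie_events], boundary.ending_frames,
        config.lag_range_seconds, config.tr_seconds,
    )
    peri_rss = peri_boundary_profile(
        [r.data for r in movie_rss], boundary.ending_frames,
        config.lag_range_seconds, config.tr_seconds,
    )
    shift_p = windowed_shift_test(
        movie_events, boundary.ending_frames,
        window_seconds=max(abs(config.boundary_window_seconds[1]), 1.0),
        n_shifts=config.n_null,
        seed=np.random.default_rng(stage_seed(config.seed, "windowed_shift")),
        tr=config.tr_seconds,
    )

    # --- event characterization ---------------------------------------------------
    labeled = [label_subject_events(ev, classification) for ev in movie_events]
    patterns: list[CoFluctuationPattern] = []
    for i, (ts, lab) in enumerate(zip(movie_scans, labeled)):
        if not lab:
            continue
        edges = edge_time_series(ts)
        patterns.extend(event_patterns(edges, lab, subject=subject_ids[i]))
    rss_by_scan = {subject_ids[i]: movie_rss[i] for i in range(len(subject_ids))}
    flat_events = [
        (subject_ids[i], f, c) for i, lab in enumerate(labeled) for f, c in lab
    ]
    amplitudes, amp_tests = amplitude_by_type(rss_by_scan, flat_events)

    similarity = None
    within_between: dict[str, tuple[float, float, float, float]] = {}
    if patterns:
        similarity = global_similarity(patterns, metric=config.similarity_metric, subjects=subject_ids)
        for t in ("boundary", "movie", "asynchronous"):
            try:
                within_between[t] = within_vs_between(similarity, t)
            except ValueError:
                pass

    boundary_patterns = [p for p in patterns if p.label == BOUNDARY]
    bpat = None
    if boundary_patterns:
        bpat = mean_pattern(
            boundary_patterns,
            movie_scans[0].system_labels,
            n_perm=max(config.n_null, 200),
            seed=np.random.default_rng(stage_seed(config.seed, "mean_pattern")),
            centroids=movie_scans[0].centroids,
            q=config.fdr_q,
        )
    peak_profiles = peak_locked_profiles(rss_by_scan, flat_events, half_window=10)
    differences = None
    n_sub_both = sum(
        1 for lab in labeled
        if {c for _, c in lab} >= {BOUNDARY, MOVIE}
    )
    if n_sub_both >= 2:
        differences = pattern_differences(patterns, (BOUNDARY, MOVIE), q=config.fdr_q)

    # --- activation analysis ------------------------------------------------------
    indicator = boundary_indicator(classification)
    maps: list[ActivationMap] = []
    system_p: dict[str, float] = {}
    stability = (np.nan, np.nan)
    if indicator.std() > 0:
        maps = [activation_map(ts, indicator) for ts in movie_scans]
        mean_map = ActivationMap(
            values=np.mean([m.values for m in maps], axis=0),
            system_labels=list(movie_scans[0].system_labels),
        )
        system_p = system_test(
            mean_map,
            centroids=movie_scans[0].centroids,
            n_perm=max(config.n_null, 200),
            seed=np.random.default_rng(stage_seed(config.seed, "system_test")),
        )
        if len(movie_scans) >= 2:
            obs, p, _ = stability_test(
                movie_scans, indicator, n_shifts=config.n_null,
                seed=np.random.default_rng(stage_seed(config.seed, "stability")),
            )
            stability = (obs, p)

    result = PipelineResult(
        config=config,
        boundary=boundary,
        movie_events=movie_events,
        rest_events=rest_events,
        movie_rss=movie_rss,
        rest_rss=rest_rss,
        classification=classification,
        lag_profile=lag_profile,
        peri_event_profile=peri_event,
        peri_rss_profile=peri_rss,
        shift_test_p=shift_p,
        labeled_events=labeled,
        patterns=patterns,
        amplitudes=amplitudes,
        amplitude_tests=amp_tests,
        similarity=similarity,
        within_between=within_between,
        boundary_pattern=bpat,
        peak_profiles=peak_profiles,
        differences=differences,
        activation_maps=maps,
        system_p=system_p,
        stability=stability,
        subject_ids=subject_ids,
    )
    if out is not None:
        _write_outputs(result, out)
    return result


def _write_outputs(res: PipelineResult, out: Path) -> None:
    (out / "events").mkdir(exist_ok=True)
    for sid, ev in zip(res.subject_ids, res.movie_events):
        esio.write_events(ev, out / "events" / f"{sid}_movie.tsv")
    for i, ev in enumerate(res.rest_events):
        esio.write_events(ev, out / "events" / f"rest{i:03d}.tsv")
    esio.write_classification(res.classification, out / "frame_classification.tsv")
    esio.write_lag_profile(res.lag_profile, out / "lag_correlation.tsv")
    esio.write_lag_profile(res.peri_event_profile, out / "peri_boundary_event_probability.tsv")
    esio.write_lag_profile(res.peri_rss_profile, out / "peri_boundary_rss.tsv")
    if res.similarity is not None:
        labels = [f"{t}:{s}" for t, s in res.similarity.block_order]
        esio.write_matrix(
            res.similarity.matrix, out / "global_similarity.tsv", row_labels=labels,
            header="# (type, subject) block similarity matrix; NaN = no event pair",
        )
    if res.boundary_pattern is not None:
        esio.write_matrix(
            res.boundary_pattern.block_means, out / "boundary_pattern_system_blocks.tsv",
            row_labels=res.boundary_pattern.systems,
            header="# system-block means of the mean boundary co-fluctuation pattern",
        )
    if res.activation_maps:
        with open(out / "activation_map.tsv", "w") as fh:
            fh.write("# per-node mean correlation with the boundary indicator\n")
            fh.write("node\tsystem\tr_mean\n")
            mean_vals = np.mean([m.values for m in res.activation_maps], axis=0)
            for i, (s, v) in enumerate(zip(res.activation_maps[0].system_labels, mean_vals)):
                fh.write(f"{i}\t{s}\t{v:.10g}\n")
    cfg = res.config
    with open(out / "run_log.txt", "w") as fh:
        fh.write("edgesync pipeline log\n")
        for key in (
            "seed", "tr_seconds", "event_alpha", "n_null", "fdr_q",
            "boundary_window_seconds", "lag_range_seconds", "similarity_metric",
        ):
            fh.write(f"{key} = {getattr(cfg, key)}\n")
        fh.write(f"windowed_shift_test_p = {res.shift_test_p}\n")
        fh.write(f"stability = {res.stability}\n")
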