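"""Readers and writers for on-disk artifacts, plus run configuration.

Conventions (declared in every output header): frame indices are 0-based,
on-disk times are in seconds, seconds convert to frames by rounding to the
nearest frame, and TSV is the canonical interchange format (``.npy`` is
accepted for large matrices).  Time-series tables have frames as rows and a
header row of node labels.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .boundaries import BoundaryAnnotation, LagProfile, convolve_boundaries
from .edgets import ParcelTimeSeries
from .events import EventSeries
from .synchrony import FrameClassification

__all__ = [
    "RunConfig",
    "stage_seed",
    "read_parcel_timeseries",
    "write_parcel_timeseries",
    "read_boundaries",
    "write_boundaries",
    "read_systems",
    "write_systems",
    "write_events",
    "write_classification",
    "write_lag_profile",
    "write_matrix",
]

FRAME_HEADER = "# frame indices are 0-based; times in seconds"


@dataclass
class RunConfig:
    """All pipeline thresholds and windows in one place.

    Defaults: event detection at alpha = 0.05 against 100 circular-shift
    nulls, FDR q = 0.05, boundary window [0, +10] s after endings, lag range
    [-20, +40] s.
    """

    tr_seconds: float = 1.0
    event_alpha: float = 0.05
    n_null: int = 100
    fdr_q: float = 0.05
    boundary_window_seconds: tuple[float, float] = (0.0, 10.0)
    lag_range_seconds: tuple[float, float] = (-20.0, 40.0)
    similarity_metric: str = "pearson"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        for name in ("event_alpha", "fdr_q"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.n_null < 1:
            raise ValueError("n_null must be a positive integer")
        self.boundary_window_seconds = tuple(self.boundary_window_seconds)  # type: ignore[assignment]
        self.lag_range_seconds = tuple(self.lag_range_seconds)  # type: ignore[assignment]
        if self.boundary_window_seconds[1] < 0:
            raise ValueError("post-ending boundary window must be >= 0")
        if not self.lag_range_seconds[0] < self.lag_range_seconds[1]:
            raise ValueError("lag range lower bound must be below upper bound")
        if self.similarity_metric not in ("pearson", "spearman", "nmi"):
            raise ValueError("similarity_metric must be pearson, spearman, or nmi")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load from a YAML mapping or plain ``key = value`` lines."""
        text = Path(path).read_text()
        try:
            data = yaml.safe_load(text)
        except yaml.YAMLError:
            data = None
        if not isinstance(data, dict):
            data = {}
            for line in text.splitlines():
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, value = line.partition("=")
                data[key.strip()] = yaml.safe_load(value.strip())
        data.update(overrides)
        known = {f for f in cls.__dataclass_fields__}  # noqa: C416
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (< 2**31) from one global seed."""
    ss = np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def _parse_numeric(df: pd.DataFrame, path: str | Path) -> np.ndarray:
    out = np.empty(df.shape, dtype=float)
    for k, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: non-numeric or missing value at row {row}, column '{col}'"
            )
        # numpy's parser is correctly rounded (full float64 round trip);
        # to_numeric above only locates offending cells
        out[:, k] = df[col].to_numpy(dtype=str).astype(np.float64)
    return out


def read_parcel_timeseries(
    path: str | Path,
    tr: float,
    system_labels: Sequence[str] | None = None,
    centroids: np.ndarray | None = None,
) -> ParcelTimeSeries:
    """Read a frames-by-nodes table (TSV with a node-label header, or .npy)."""
    path = Path(path)
    if path.suffix == ".npy":
        data = np.load(path)
        labels = [f"node{i}" for i in range(data.shape[1])]
    else:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        labels = [str(c) for c in df.columns]
        data = _parse_numeric(df, path)
    if data.shape[0] < 3:
        raise ValueError(f"{path}: need at least 3 frames, got {data.shape[0]}")
    ts = ParcelTimeSeries(
        data=data,
        tr_seconds=tr,
        node_labels=labels,
        system_labels=list(system_labels) if system_labels else [],
        centroids=centroids,
    )
    sd = ts.data.std(axis=0, ddof=1)
    if np.any(sd == 0):
        import warnings

        bad = [labels[i] for i in np.flatnonzero(sd == 0)[:5]]
        warnings.warn(f"{path}: zero-variance column(s) {bad}; z-scoring will reject them")
    return ts


def write_parcel_timeseries(ts: ParcelTimeSeries, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".npy":
        np.save(path, ts.data)
        return
    with open(path, "w") as fh:
        fh.write(FRAME_HEADER + "; frames as rows, nodes as columns\n")
        fh.write("\t".join(str(c) for c in ts.node_labels) + "\n")
        np.savetxt(fh, ts.data, delimiter="\t", fmt="%.17g")


def read_boundaries(path: str | Path, tr: float, n_frames: int) -> BoundaryAnnotation:
    """Read coded scene-ending times; the header column name declares the unit.

    Accepts one- or two-column TSV; the time column is named either
    ``time_seconds`` (converted by nearest-frame rounding) or ``frame``.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = {c.lower(): c for c in df.columns}
    if "time_seconds" in cols:
        frames = np.round(df[cols["time_seconds"]].to_numpy(dtype=float) / tr).astype(int)
    elif "frame" in cols:
        frames = df[cols["frame"]].to_numpy(dtype=int)
    else:
        raise ValueError(f"{path}: need a 'time_seconds' or 'frame' column declaring the unit")
    if frames.size and (frames.min() < 0 or frames.max() >= n_frames):
        raise ValueError(f"{path}: boundary outside [0, {n_frames}) frames")
    if frames.size > 1 and np.any(np.diff(frames) <= 0):
        raise ValueError(f"{path}: boundary times must be strictly increasing")
    return convolve_boundaries(frames, n_frames, tr)


def write_boundaries(frames: np.ndarray, tr: float, path: str | Path, scan_id: str = "movie") -> None:
    with open(path, "w") as fh:
        fh.write(FRAME_HEADER + "\n")
        fh.write("scan_id\ttime_seconds\n")
        for f in frames:
            fh.write(f"{scan_id}\t{f * tr:.6g}\n")


def read_systems(path: str | Path) -> dict[str, str]:
    """Two-column TSV (node_label, system_label) -> mapping."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (node_label, system_label)")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def write_systems(node_labels: Sequence[str], system_labels: Sequence[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("node_label\tsystem_label\n")
        for n, s in zip(node_labels, system_labels):
            fh.write(f"{n}\t{s}\n")


def write_events(events: EventSeries, path: str | Path, mark_runs: np.ndarray | None = None) -> None:
    is_peak = np.zeros(events.n_frames, dtype=int)
    if len(events.peak_frames):
        is_peak[events.peak_frames] = 1
    is_event = events.frames if mark_runs is None else mark_runs
    with open(path, "w") as fh:
        fh.write(FRAME_HEADER + "\n")
        fh.write("frame\tis_event\tis_peak\n")
        for t in range(events.n_frames):
            fh.write(f"{t}\t{int(is_event[t])}\t{int(is_peak[t])}\n")


def write_classification(fc: FrameClassification, path: str | Path) -> None:
    labels = fc.labels if fc.labels is not None else np.full(fc.n_frames, "", dtype=object)
    with open(path, "w") as fh:
        fh.write(FRAME_HEADER + "\n")
        fh.write("frame\tfraction\tp\tq_sig\tlabel\n")
        for t in range(fc.n_frames):
            fh.write(
                f"{t}\t{fc.fraction_with_event[t]:.10g}\t{fc.p_values[t]:.10g}"
                f"\t{int(fc.significant[t])}\t{labels[t]}\n"
            )


def write_lag_profile(profile: LagProfile, path: str | Path) -> None:
    n_obs = profile.n_observations
    with open(path, "w") as fh:
        fh.write(FRAME_HEADER + "\n")
        fh.write("lag_seconds\tvalue\tn_observations\n")
        for i in range(profile.lags_seconds.shape[0]):
            n = "" if n_obs is None else int(n_obs[i])
            fh.write(f"{profile.lags_seconds[i]:.10g}\t{profile.values[i]:.10g}\t{n}\n")


def write_matrix(
    matrix: np.ndarray,
    path: str | Path,
    row_labels: Sequence[str] | None = None,
    header: str | None = None,
) -> None:
    with open(path, "w") as fh:
        fh.write((header or FRAME_HEADER) + "\n")
        if row_labels is not None:
            fh.write("\t".join(str(r) for r in row_labels) + "\n")
        np.savetxt(fh, matrix, delimiter="\t", fmt="%.10g")


def read_matrix(path: str | Path, has_labels: bool = False) -> np.ndarray:
    skip = 2 if has_labels else 1
    return np.loadtxt(path, delimiter="\t", skiprows=skip)


def read_clip_windows(path: str | Path) -> list[tuple[int, int]]:
    """TSV (scan_id, start_frame, end_frame), half-open [start, end)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return [(int(r.start_frame), int(r.end_frame)) for r in df.itertuples()]


def save_simulation(sim, out_dir: str | Path) -> None:
    """Write one simulated group (or list of viewings) in the conventional layout.

    ``movie/`` and ``rest/`` hold one TSV per subject (suffixed ``_v<k>``
    for repeated viewings), alongside ``truth.tsv`` (subject, condition,
    frame, label), ``boundaries.tsv``, ``systems.tsv`` and ``centroids.tsv``.
    """
    out = Path(out_dir)
    (out / "movie").mkdir(parents=True, exist_ok=True)
    (out / "rest").mkdir(parents=True, exist_ok=True)
    sims = sim if isinstance(sim, list) else [sim]
    truths = []
    for v, one in enumerate(sims):
        suffix = f"_v{v}" if len(sims) > 1 else ""
        for s, ts in enumerate(one.movie_scans):
            write_parcel_timeseries(ts, out / "movie" / f"sub{s:03d}{suffix}.tsv")
        n_rest = max(one.spec.n_rest_scans, 1)
        for i, ts in enumerate(one.rest_scans):
            s, r = divmod(i, n_rest)
            write_parcel_timeseries(ts, out / "rest" / f"sub{s:03d}_r{r}{suffix}.tsv")
        truth = one.truth.copy()
        truth.insert(0, "viewing", v)
        truths.append(truth)
    first = sims[0]
    pd.concat(truths, ignore_index=True).to_csv(out / "truth.tsv", sep="\t", index=False)
    write_boundaries(first.boundary_frames, first.spec.tr_seconds, out / "boundaries.tsv")
    ts0 = first.movie_scans[0]
    write_systems(ts0.node_labels, ts0.system_labels, out / "systems.tsv")
    if first.centroids is not None:
        with open(out / "centroids.tsv", "w") as fh:
            fh.write("x\ty\tz\n")
            np.savetxt(fh, first.centroids, delimiter="\t", fmt="%.10g")


def manifest_from_dir(data_dir: str | Path) -> Mapping[str, object]:
    """Discover the conventional layout written by ``edgesync simulate``."""
    data_dir = Path(data_dir)
    movie = sorted((data_dir / "movie").glob("*.tsv"))
    rest = sorted((data_dir / "rest").glob("*.tsv"))
    manifest: dict[str, object] = {"movie": movie, "rest": rest}
    if (data_dir / "boundaries.tsv").exists():
        manifest["boundaries"] = data_dir / "boundaries.tsv"
    if (data_dir / "systems.tsv").exists():
        manifest["systems"] = data_dir / "systems.tsv"
    if (data_dir / "centroids.tsv").exists():
        manifest["centroids"] = np.loadtxt(data_dir / "centroids.tsv", delimiter="\t", skiprows=1)
    return manifest
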