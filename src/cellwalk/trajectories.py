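"""Single-cell track kinematics.

A *trajectory* is one cell's time-ordered 2-D positions (minutes, µm).
From it we derive the quantities used throughout migration analysis:

* step lengths — Euclidean distance moved between consecutive frames
  (Pythagoras on the x/y increments);
* total displacement — the cumulative path length, i.e. the overall
  distance the cell moved (the figure-legend convention in live-cell
  tracking work), as opposed to the straight-line *net* displacement;
* mean speed — path length divided by tracked duration, used to filter
  out stationary debris (kept only if strictly above a threshold,
  2.5 µm/min by default);
* origin-anchored coordinates for rose plots; and
* per-condition cumulative-distance matrices feeding the time-course
  rank-sum scan.

Tracks may have missing frames: steps are computed across the gap and
speeds are normalised by the actual elapsed time.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    DataError,
    FormatError,
    InsufficientDataError,
    ParameterError,
)

logger = logging.getLogger(__name__)

TRACK_COLUMNS = ("track_id", "t_min", "x_um", "y_um")


@dataclass(frozen=True)
class Trajectory:
    """One cell's track: strictly increasing times (min) and planar positions (µm)."""

    track_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    frame_interval: float

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if t.size < 2:
            raise InsufficientDataError(
                f"track {self.track_id!r}: need >=2 points, got {t.size}"
            )
        if not (t.size == x.size == y.size):
            raise DataError(f"track {self.track_id!r}: t/x/y length mismatch")
        if np.any(np.diff(t) <= 0):
            raise DataError(f"track {self.track_id!r}: times not strictly increasing")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise DataError(f"track {self.track_id!r}: non-finite coordinates")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def n_points(self) -> int:
        return int(self.t.size)

    @property
    def duration(self) -> float:
        """Tracked duration in minutes."""
        return float(self.t[-1] - self.t[0])


@dataclass(frozen=True)
class StepSeries:
    """Per-frame-pair step lengths (µm) of one track."""

    track_id: str
    steps: np.ndarray
    dt: np.ndarray  # elapsed minutes per step (>frame interval across gaps)

    def __post_init__(self):
        steps = np.asarray(self.steps, dtype=float)
        if np.any(steps < 0):
            raise DataError("negative step length")
        object.__setattr__(self, "steps", steps)
        object.__setattr__(self, "dt", np.asarray(self.dt, dtype=float))


@dataclass(frozen=True)
class KinematicsSummary:
    track_id: str
    total_displacement: float  # cumulative path length, µm
    net_displacement: float  # straight-line start->end, µm
    median_step_length: float  # µm
    mean_speed: float  # µm/min (path length / duration)
    duration: float  # minutes
    n_points: int


@dataclass(frozen=True)
class TrackFilterConfig:
    """Speed/length filter applied to tracks.

    ``min_mean_speed`` is strict ("above"): a track at exactly the
    threshold is rejected.  ``object_size_um`` records the imaging-side
    segmentation size filter for provenance only; it is never applied
    here (no images pass through this pipeline).
    """

    min_mean_speed: float = 2.5  # µm/min
    min_track_length: int = 2  # frames
    object_size_um: float | None = 25.0  # provenance only

    def __post_init__(self):
        if self.min_mean_speed < 0:
            raise ParameterError("min_mean_speed must be >= 0")
        if self.min_track_length < 2:
            raise ParameterError("min_track_length must be >= 2")


@dataclass
class CumulativeDistanceMatrix:
    """Per-track cumulative distances aligned on shared acquisition times.

    ``series`` maps track id -> non-decreasing cumulative distances whose
    k-th entry is the distance travelled by time ``times[k]``; ragged
    lengths encode tracks that end early.
    """

    condition: str
    frame_interval: float
    times: np.ndarray = field(default_factory=lambda: np.array([]))
    series: dict[str, np.ndarray] = field(default_factory=dict)

    def n_tracked_at(self, k: int) -> int:
        """Number of tracks still tracked at time index ``k``."""
        return sum(1 for s in self.series.values() if s.size > k)

    def values_at(self, k: int) -> np.ndarray:
        """Cumulative distances of tracks surviving to time index ``k``."""
        return np.array([s[k] for s in self.series.values() if s.size > k])


def load_tracks(path, frame_interval: float) -> list[Trajectory]:
    """Read a track table CSV (``track_id,t_min,x_um,y_um``) into Trajectories.

    Rows with missing coordinates are dropped (count logged); duplicated
    (track, time) rows raise :class:`DataError` naming the track.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    n_before = len(df)
    df = df.dropna(subset=["x_um", "y_um", "t_min"])
    if len(df) < n_before:
        logger.info("%s: dropped %d rows with missing coordinates", path, n_before - len(df))
    trajs = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("t_min")
        if grp["t_min"].duplicated().any():
            t_dup = grp.loc[grp["t_min"].duplicated(), "t_min"].iloc[0]
            raise DataError(f"duplicate time point t={t_dup} in track {tid!r}")
        trajs.append(
            Trajectory(
                track_id=str(tid),
                t=grp["t_min"].to_numpy(float),
                x=grp["x_um"].to_numpy(float),
                y=grp["y_um"].to_numpy(float),
                frame_interval=frame_interval,
            )
        )
    return trajs


def save_tracks(trajs: Iterable[Trajectory], path) -> None:
    """Write trajectories in the CSV dialect read by :func:`load_tracks`."""
    frames = [
        pd.DataFrame(
            {"track_id": tr.track_id, "t_min": tr.t, "x_um": tr.x, "y_um": tr.y}
        )
        for tr in trajs
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def step_lengths(traj: Trajectory) -> StepSeries:
    """Euclidean step per consecutive frame pair: c = sqrt(a² + b²)."""
    dx = np.diff(traj.x)
    dy = np.diff(traj.y)
    return StepSeries(
        track_id=traj.track_id,
        steps=np.hypot(dx, dy),
        dt=np.diff(traj.t),
    )


def kinematics_summary(traj: Trajectory) -> KinematicsSummary:
    """Summary statistics of one track (path length, net displacement, speed)."""
    ss = step_lengths(traj)
    total = float(ss.steps.sum())
    net = float(math.hypot(traj.x[-1] - traj.x[0], traj.y[-1] - traj.y[0]))
    duration = traj.duration
    return KinematicsSummary(
        track_id=traj.track_id,
        total_displacement=total,
        net_displacement=net,
        median_step_length=float(np.median(ss.steps)),
        mean_speed=total / duration,
        duration=duration,
        n_points=traj.n_points,
    )


def summaries_frame(trajs: Iterable[Trajectory]) -> pd.DataFrame:
    """Kinematics summaries of a cohort as one row per track."""
    rows = [kinematics_summary(tr).__dict__ for tr in trajs]
    return pd.DataFrame(rows)


def filter_tracks(
    trajs: Iterable[Trajectory], cfg: TrackFilterConfig | None = None
) -> tuple[list[Trajectory], list[tuple[Trajectory, str]]]:
    """Partition tracks into (kept, rejected-with-reason) under ``cfg``.

    Kept iff mean speed is strictly above ``cfg.min_mean_speed`` and the
    track has at least ``cfg.min_track_length`` points.
    """
    cfg = cfg or TrackFilterConfig()
    kept: list[Trajectory] = []
    rejected: list[tuple[Trajectory, str]] = []
    for tr in trajs:
        if tr.n_points < cfg.min_track_length:
            rejected.append((tr, f"short-track ({tr.n_points} < {cfg.min_track_length} frames)"))
            continue
        speed = kinematics_summary(tr).mean_speed
        if speed <= cfg.min_mean_speed:
            rejected.append(
                (tr, f"slow-track (mean speed {speed:.3g} <= {cfg.min_mean_speed} um/min)")
            )
            continue
        kept.append(tr)
    for _, reason in rejected:
        logger.debug("rejected track: %s", reason)
    logger.info("filter_tracks: kept %d, rejected %d", len(kept), len(rejected))
    return kept, rejected


def to_origin(
    trajs: Sequence[Trajectory],
    n_select: int | None = None,
    seed: int | None = None,
) -> list[Trajectory]:
    """Translate tracks so each starts at (0,0); optionally sample for rose plots.

    When ``n_select`` is given, that many tracks are chosen at random
    (reproducibly under ``seed``), mirroring the convention of plotting
    20 randomly chosen cells per rose plot.
    """
    trajs = list(trajs)
    if n_select is not None and n_select < len(trajs):
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(trajs), size=n_select, replace=False)
        trajs = [trajs[i] for i in sorted(idx)]
    return [
        Trajectory(
            track_id=tr.track_id,
            t=tr.t,
            x=tr.x - tr.x[0],
            y=tr.y - tr.y[0],
            frame_interval=tr.frame_interval,
        )
        for tr in trajs
    ]


def cumulative_distance_matrix(
    trajs: Iterable[Trajectory], condition: str
) -> CumulativeDistanceMatrix:
    """Per-track cumulative path length on the shared acquisition grid.

    Entry (cell, k) is the distance travelled over the first k frames;
    ragged track lengths are preserved.  Tracks must share a frame
    interval, otherwise :class:`AlignmentError` is raised.
    """
    trajs = list(trajs)
    if not trajs:
        return CumulativeDistanceMatrix(condition=condition, frame_interval=float("nan"))
    intervals = {tr.frame_interval for tr in trajs}
    if len(intervals) != 1:
        raise AlignmentError(f"inconsistent frame intervals: {sorted(intervals)}")
    interval = intervals.pop()
    series: dict[str, np.ndarray] = {}
    max_len = 0
    for tr in trajs:
        cum = np.concatenate([[0.0], np.cumsum(step_lengths(tr).steps)])
        series[tr.track_id] = cum
        max_len = max(max_len, cum.size)
    times = np.arange(max_len) * interval
    return CumulativeDistanceMatrix(
        condition=condition, frame_interval=interval, times=times, series=series
    )
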