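"""Motility metrics from time-stamped centroid tracks.

Live-cell validation assays summarize each tracked cell with three
numbers: **velocity**, the net start-to-end displacement divided by
elapsed time (directional progress); **origin of distance**, the
straight-line distance from the starting point to the cell's position
(reported at the final point unless a per-frame series is requested);
and **speed**, the summed point-to-point path length divided by elapsed
time. Speed >= velocity for every track, with equality only on straight
constant-direction paths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Frame interval of the live-cell acquisitions (seconds).
DEFAULT_FRAME_INTERVAL_S = 50.0


class TrackError(ValueError):
    """Raised for tracks that cannot be measured."""


@dataclass
class Track:
    """Ordered (t, x, y) samples for one cell."""

    track_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.size == self.x.size == self.y.size):
            raise TrackError("t, x, y must have equal lengths")
        if self.t.size < 2:
            raise TrackError("a track needs at least 2 points")
        if not np.all(np.diff(self.t) > 0):
            raise TrackError("track times must be strictly increasing")

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass
class TrackMetrics:
    track_id: str
    velocity: float
    origin_of_distance: float
    speed: float
    duration: float
    n_points: int

    def as_dict(self) -> dict:
        return {
            "track_id": self.track_id,
            "velocity": self.velocity,
            "origin_of_distance": self.origin_of_distance,
            "speed": self.speed,
            "duration": self.duration,
            "n_points": self.n_points,
        }


def track_metrics(track: Track) -> TrackMetrics:
    """Compute velocity, origin of distance and speed for one track."""
    dx = track.x[-1] - track.x[0]
    dy = track.y[-1] - track.y[0]
    net = float(np.hypot(dx, dy))
    steps = np.hypot(np.diff(track.x), np.diff(track.y))
    path = float(steps.sum())
    dt = track.duration
    return TrackMetrics(
        track_id=track.track_id,
        velocity=net / dt,
        origin_of_distance=net,
        speed=path / dt,
        duration=dt,
        n_points=int(track.t.size),
    )


def origin_of_distance_series(track: Track) -> pd.DataFrame:
    """Per-frame distance from the starting point (the --per-frame view)."""
    d = np.hypot(track.x - track.x[0], track.y - track.y[0])
    return pd.DataFrame({"t": track.t, "origin_of_distance": d})


def tracks_from_frame(df: pd.DataFrame) -> list[Track]:
    """Parse a (track_id, t, x, y) table into Track objects."""
    required = {"track_id", "t", "x", "y"}
    if not required.issubset(df.columns):
        raise TrackError(f"track table needs columns {sorted(required)}")
    tracks = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("t")
        tracks.append(
            Track(str(tid), grp["t"].to_numpy(), grp["x"].to_numpy(), grp["y"].to_numpy())
        )
    return tracks


def measure_tracks(
    df: pd.DataFrame, *, min_duration: float = 0.0
) -> pd.DataFrame:
    """Per-track metrics table; tracks shorter than ``min_duration`` are
    excluded from the output (and hence from population summaries)."""
    rows = [
        track_metrics(tr).as_dict()
        for tr in tracks_from_frame(df)
        if tr.duration >= min_duration
    ]
    return pd.DataFrame(rows)


def population_summary(metrics: pd.DataFrame) -> dict:
    """Mean and SD of each motility metric over the track population."""
    out: dict = {"n_tracks": int(len(metrics))}
    for col in ("velocity", "origin_of_distance", "speed"):
        out[f"{col}_mean"] = float(metrics[col].mean())
        out[f"{col}_sd"] = float(metrics[col].std(ddof=1)) if len(metrics) > 1 else 0.0
    return out
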