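"""Open-field locomotion analysis.

Instantaneous speed over a trailing 4-frame sliding window, running-episode
detection above a 5 cm/s threshold, average running speed (running distance
divided by running time), total distance, and center-zone occupancy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class Trajectory:
    """Calibrated (cm) top-view trajectory in a rectangular arena.

    ``center_frac`` defines the central zone as that fraction of each arena
    side (default: central 50% rectangle).
    """

    x: np.ndarray
    y: np.ndarray
    frame_rate: float
    arena: tuple[float, float] = (50.0, 50.0)
    center_frac: float = 0.5

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if len(self.x) != len(self.y):
            raise ValueError("x and y must have equal length")
        w, h = self.arena
        eps = 1e-9
        if (np.any(self.x < -eps) or np.any(self.x > w + eps)
                or np.any(self.y < -eps) or np.any(self.y > h + eps)):
            raise ValueError("positions fall outside the arena")

    @property
    def n_frames(self) -> int:
        return len(self.x)

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate

    def step_lengths(self) -> np.ndarray:
        """Per-frame displacement (cm); length n_frames-1."""
        return np.hypot(np.diff(self.x), np.diff(self.y))

    def total_distance(self) -> float:
        return float(self.step_lengths().sum())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"frame": np.arange(self.n_frames),
                      "x_cm": self.x, "y_cm": self.y}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, frame_rate: float,
                 arena: tuple[float, float] = (50.0, 50.0),
                 center_frac: float = 0.5) -> "Trajectory":
        """Read a trajectory CSV; accepts ``x_cm/y_cm`` or plain ``x/y``
        columns (tracking-export dialects vary)."""
        df = pd.read_csv(path)
        cols = {c.lower().strip(): c for c in df.columns}
        for xc, yc in (("x_cm", "y_cm"), ("x", "y")):
            if xc in cols and yc in cols:
                return cls(x=df[cols[xc]].to_numpy(float),
                           y=df[cols[yc]].to_numpy(float),
                           frame_rate=frame_rate, arena=arena,
                           center_frac=center_frac)
        raise ValueError(f"no x/y columns found in {path} "
                         f"(columns: {list(df.columns)})")


def instant_velocity(traj: Trajectory, window_frames: int = 4) -> np.ndarray:
    """Sliding-window speed (cm/s) per frame.

    The speed at frame ``i`` is the path length over the trailing window
    spanning frames ``[i - window_frames + 1, i]`` divided by the window
    duration (``window_frames - 1`` frame periods). The first
    ``window_frames - 1`` values are NaN.
    """
    if window_frames < 2:
        raise ValueError("window_frames must be >= 2")
    if traj.n_frames < window_frames:
        raise ValueError(f"trajectory has {traj.n_frames} frames; "
                         f"need >= {window_frames}")
    steps = traj.step_lengths()
    k = window_frames - 1
    cs = np.concatenate([[0.0], np.cumsum(steps)])
    path = cs[k:] - cs[:-k]                      # window path length per frame
    duration = k / traj.frame_rate
    speed = np.full(traj.n_frames, np.nan)
    speed[k:] = path / duration
    return speed


@dataclass
class Episode:
    """A maximal run of frames with speed above threshold."""

    start_frame: int
    end_frame: int                 # inclusive
    duration_s: float
    distance_cm: float


@dataclass
class EpisodeSummary:
    """Running-episode summary for one trajectory."""

    episodes: list[Episode]
    total_distance_cm: float       # whole trajectory
    running_time_s: float
    running_distance_cm: float
    avg_running_speed_cm_s: float  # NaN when the animal never ran

    @property
    def n_episodes(self) -> int:
        return len(self.episodes)


def detect_episodes(speed: np.ndarray, frame_rate: float,
                    threshold: float = 5.0,
                    total_distance_cm: float | None = None) -> EpisodeSummary:
    """Detect running episodes as maximal runs of frames with speed strictly
    above ``threshold`` (cm/s).

    Average running speed is the distance covered while running divided by
    the time spent running; each running frame contributes one frame period
    at its instantaneous speed.
    """
    speed = np.asarray(speed, float)
    dt = 1.0 / frame_rate
    running = np.zeros(len(speed), bool)
    valid = ~np.isnan(speed)
    running[valid] = speed[valid] > threshold

    edges = np.flatnonzero(np.diff(np.concatenate([[0], running.view(np.int8), [0]])))
    episodes = []
    for s, e in zip(edges[::2], edges[1::2]):      # [s, e) runs
        dist = float(np.sum(speed[s:e]) * dt)
        episodes.append(Episode(start_frame=int(s), end_frame=int(e - 1),
                                duration_s=(e - s) * dt, distance_cm=dist))
    run_time = float(running.sum() * dt)
    run_dist = float(sum(ep.distance_cm for ep in episodes))
    avg = run_dist / run_time if run_time > 0 else float("nan")
    if total_distance_cm is None:
        total_distance_cm = float(np.nansum(speed * dt))
    return EpisodeSummary(episodes=episodes, total_distance_cm=total_distance_cm,
                          running_time_s=run_time, running_distance_cm=run_dist,
                          avg_running_speed_cm_s=avg)


def center_time(traj: Trajectory) -> float:
    """Seconds spent inside the central zone (closed bounds: frames on the
    zone border count as inside)."""
    w, h = traj.arena
    fx = traj.center_frac
    if not 0 < fx <= 1:
        raise ValueError("center_frac must be in (0, 1]")
    x0, x1 = w * (1 - fx) / 2, w * (1 + fx) / 2
    y0, y1 = h * (1 - fx) / 2, h * (1 + fx) / 2
    inside = ((traj.x >= x0) & (traj.x <= x1)
              & (traj.y >= y0) & (traj.y <= y1))
    return float(inside.sum() / traj.frame_rate)


def summarize(traj: Trajectory, threshold: float = 5.0,
              window_frames: int = 4) -> pd.DataFrame:
    """One-row kinematics summary table for a trajectory."""
    speed = instant_velocity(traj, window_frames)
    summ = detect_episodes(speed, traj.frame_rate, threshold,
                           total_distance_cm=traj.total_distance())
    return pd.DataFrame([{
        "distance_m": summ.total_distance_cm / 100.0,
        "mean_velocity_cm_s": summ.avg_running_speed_cm_s,
        "episodes": summ.n_episodes,
        "running_time_s": summ.running_time_s,
        "center_time_s": center_time(traj),
    }])
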