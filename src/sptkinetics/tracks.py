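"""Core containers for single-particle-tracking data.

A :class:`Trajectory` is one molecule's time-ordered sequence of 2D
localizations; a :class:`TrajectorySet` bundles trajectories recorded at a
common frame interval. Positions are in micrometres throughout, frame
indices are integers and time is ``frame * dt`` seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "TrajectorySet",
    "read_trajectory_csv",
    "write_trajectory_csv",
    "read_localization_csv",
    "write_localization_csv",
]

#: column order of the trajectory CSV interchange format
TRAJECTORY_COLUMNS = ["track_id", "frame", "x_um", "y_um"]
#: column order of the localization CSV interchange format
LOCALIZATION_COLUMNS = ["frame", "x_um", "y_um"]

# 7 significant digits keeps sub-nanometre precision for micrometre positions
_FLOAT_FMT = "%.7g"


@dataclass(frozen=True)
class Trajectory:
    """One molecule's gapless, time-ordered 2D track.

    Parameters
    ----------
    track_id
        Unique identifier within a :class:`TrajectorySet`.
    frames
        Strictly increasing integer frame indices with unit spacing.
    x, y
        Positions in micrometres, one per frame.
    """

    track_id: int
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=np.int64)
        x = np.asarray(self.x, dtype=np.float64)
        y = np.asarray(self.y, dtype=np.float64)
        if not (len(frames) == len(x) == len(y)):
            raise ValueError("frames, x and y must have equal length")
        if len(frames) < 2:
            raise ValueError("a trajectory needs at least 2 positions")
        d = np.diff(frames)
        if np.any(d <= 0):
            raise ValueError("frames must be strictly increasing")
        if np.any(d != 1):
            raise ValueError("trajectory has frame gaps; only gapless tracks are supported")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    def __len__(self) -> int:
        return len(self.frames)

    def displacements(self, lag: int = 1) -> np.ndarray:
        """Euclidean jump lengths between positions ``lag`` frames apart (µm)."""
        if lag < 1 or lag >= len(self):
            return np.empty(0)
        dx = self.x[lag:] - self.x[:-lag]
        dy = self.y[lag:] - self.y[:-lag]
        return np.hypot(dx, dy)


@dataclass
class TrajectorySet:
    """A collection of trajectories sharing one frame interval ``dt`` (s)."""

    trajectories: list[Trajectory]
    dt: float
    condition_label: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        ids = [t.track_id for t in self.trajectories]
        if len(ids) != len(set(ids)):
            raise ValueError("track_ids must be unique")

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self) -> Iterator[Trajectory]:
        return iter(self.trajectories)

    def n_localizations(self) -> int:
        return sum(len(t) for t in self.trajectories)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns ``track_id, frame, x_um, y_um``."""
        if not self.trajectories:
            return pd.DataFrame(columns=TRAJECTORY_COLUMNS)
        parts = [
            pd.DataFrame(
                {"track_id": t.track_id, "frame": t.frames, "x_um": t.x, "y_um": t.y}
            )
            for t in self.trajectories
        ]
        return pd.concat(parts, ignore_index=True)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, dt: float, condition_label: str = ""
    ) -> "TrajectorySet":
        missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing trajectory columns: {missing}")
        trajs = []
        for tid, grp in df.groupby("track_id", sort=True):
            grp = grp.sort_values("frame")
            trajs.append(
                Trajectory(
                    track_id=int(tid),
                    frames=grp["frame"].to_numpy(),
                    x=grp["x_um"].to_numpy(),
                    y=grp["y_um"].to_numpy(),
                )
            )
        return cls(trajectories=trajs, dt=dt, condition_label=condition_label)


def write_trajectory_csv(trajs: TrajectorySet, path: str | Path) -> None:
    trajs.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_trajectory_csv(path: str | Path, dt: float, condition_label: str = "") -> TrajectorySet:
    df = pd.read_csv(path)
    return TrajectorySet.from_frame(df, dt=dt, condition_label=condition_label)


def write_localization_csv(locs: pd.DataFrame, path: str | Path) -> None:
    locs[LOCALIZATION_COLUMNS].to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_localization_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in LOCALIZATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing localization columns: {missing}")
    if (df["frame"] < 0).any():
        raise ValueError("negative frame indices in localization table")
    return df
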