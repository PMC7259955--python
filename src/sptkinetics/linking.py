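"""Frame-to-frame linking of localizations into trajectories.

Emulates the tracking stage of a typical SPT pipeline: per frame pair,
detections are matched by optimal (Hungarian) assignment minimizing total
squared displacement, subject to a hard maximum-jump gate expressed in
pixels. Unmatched detections start new tracks; a track with no match in the
next frame terminates (no gap closing). The assignment uses the standard
augmented cost matrix in which leaving a detection unmatched costs the
squared gate radius, so a link is always preferred to a birth/death pair
whenever it is geometrically allowed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .tracks import TrajectorySet, Trajectory

__all__ = ["LinkConfig", "link_localizations", "filter_min_length"]

logger = logging.getLogger(__name__)

_FORBIDDEN = 1e12  # cost for pairs beyond the gate; never selected (births are cheaper)


@dataclass(frozen=True)
class LinkConfig:
    """Linking parameters.

    ``max_jump_px`` is the gate radius in camera pixels (the field's tracking
    tools express it this way); ``min_track_len`` is 3 for jump-distribution
    analysis and 6 for MSD analysis.
    """

    max_jump_px: float = 5.0
    pixel_size: float = 0.107
    min_track_len: int = 3

    def __post_init__(self) -> None:
        if self.max_jump_px <= 0:
            raise ValueError("max_jump_px must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.min_track_len < 2:
            raise ValueError("min_track_len must be >= 2")

    @property
    def max_jump_um(self) -> float:
        return self.max_jump_px * self.pixel_size


def _assign(prev: np.ndarray, nxt: np.ndarray, r_max: float) -> list[tuple[int, int]]:
    """Optimal gated matching between two frames' detections.

    Returns (i, j) index pairs into ``prev`` and ``nxt``. Cost: squared
    distance for allowed links, r_max² per unmatched detection (birth/death).
    """
    n1, n2 = len(prev), len(nxt)
    if n1 == 0 or n2 == 0:
        return []
    d2 = ((prev[:, None, :] - nxt[None, :, :]) ** 2).sum(axis=2)
    gate = r_max**2
    cost = np.full((n1 + n2, n2 + n1), 0.0)
    link = np.where(d2 <= gate, d2, _FORBIDDEN)
    cost[:n1, :n2] = link
    cost[:n1, n2:] = _FORBIDDEN
    cost[n1:, :n2] = _FORBIDDEN
    np.fill_diagonal(cost[:n1, n2:], gate)  # death of a previous-frame track
    np.fill_diagonal(cost[n1:, :n2], gate)  # birth of a next-frame track
    rows, cols = linear_sum_assignment(cost)
    return [(int(i), int(j)) for i, j in zip(rows, cols)
            if i < n1 and j < n2 and d2[i, j] <= gate]


def link_localizations(locs: pd.DataFrame, config: LinkConfig | None = None,
                       dt: float = 0.010) -> TrajectorySet:
    """Assemble a localization table (frame, x_um, y_um) into trajectories.

    Deterministic and input-order independent: detections are sorted by
    (frame, x, y) before assignment. Empty input yields an empty set.
    """
    config = config or LinkConfig()
    if len(locs) == 0:
        return TrajectorySet(trajectories=[], dt=dt)
    if (locs["frame"] < 0).any():
        raise ValueError("negative frame indices in localization table")
    locs = locs.sort_values(["frame", "x_um", "y_um"], kind="mergesort").reset_index(drop=True)
    r_max = config.max_jump_um

    frames = locs["frame"].to_numpy(dtype=np.int64)
    xy = locs[["x_um", "y_um"]].to_numpy(dtype=float)
    unique_frames = np.unique(frames)

    # active track state: list of (point-list, last frame)
    open_tracks: dict[int, list[int]] = {}  # track id -> row indices
    track_last: dict[int, int] = {}
    closed: list[list[int]] = []
    next_id = 0
    prev_rows: np.ndarray | None = None
    prev_ids: list[int] = []
    prev_frame = None

    for f in unique_frames:
        rows = np.flatnonzero(frames == f)
        if prev_frame is not None and f == prev_frame + 1 and prev_rows is not None:
            pairs = _assign(xy[prev_rows], xy[rows], r_max)
        else:
            pairs = []  # a skipped frame terminates everything (no gap closing)
        matched_prev = {i for i, _ in pairs}
        matched_next = {j for _, j in pairs}
        # terminate unmatched previous tracks
        for idx, tid in enumerate(prev_ids):
            if idx not in matched_prev:
                closed.append(open_tracks.pop(tid))
        # extend matched tracks
        new_ids = [-1] * len(rows)
        for i, j in pairs:
            tid = prev_ids[i]
            open_tracks[tid].append(int(rows[j]))
            new_ids[j] = tid
        # births
        for j in range(len(rows)):
            if j not in matched_next:
                open_tracks[next_id] = [int(rows[j])]
                new_ids[j] = next_id
                next_id += 1
        prev_rows = rows
        prev_ids = new_ids
        prev_frame = f
    closed.extend(open_tracks.values())

    trajs = []
    tid = 0
    for row_idx in closed:
        if len(row_idx) < config.min_track_len:
            continue
        idx = np.asarray(row_idx)
        trajs.append(Trajectory(track_id=tid, frames=frames[idx],
                                x=xy[idx, 0], y=xy[idx, 1]))
        tid += 1
    trajs.sort(key=lambda t: (t.frames[0], t.x[0], t.y[0]))
    trajs = [Trajectory(track_id=i, frames=t.frames, x=t.x, y=t.y)
             for i, t in enumerate(trajs)]
    logger.info("linked %d localizations into %d tracks (>= %d frames)",
                len(locs), len(trajs), config.min_track_len)
    return TrajectorySet(trajectories=trajs, dt=dt)


def filter_min_length(trajs: TrajectorySet, min_len: int) -> TrajectorySet:
    """Keep only trajectories with at least ``min_len`` positions."""
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    kept = [t for t in trajs if len(t) >= min_len]
    logger.info("length filter >= %d frames: %d of %d tracks kept",
                min_len, len(kept), len(trajs))
    return TrajectorySet(trajectories=kept, dt=trajs.dt,
                         condition_label=trajs.condition_label,
                         provenance=dict(trajs.provenance))
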