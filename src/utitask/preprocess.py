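"""Trajectory preprocessing: per-trial coordinate remapping, mirroring,
and 101-point resampling.

The task records the cursor at 100 Hz from the moment it leaves the
start button until a response box is clicked.  Downstream geometry uses
two frames:

pixel frame
    Raw screen pixels (y grows downward).  The signed maximum absolute
    deviation is reported in this frame, matching how mouse-tracking
    curvature is conventionally reported (px).
unit frame
    A per-trial affine map sends the observed start point to (0, 0) and
    the observed click pixel to (-1, 1) for a left response or (1, 1)
    for a right response.  Because the response boxes sit at the top of
    the screen, the map flips the y axis: "up" is positive afterwards.
    This frame is used for averaging and plotting across trials.

Spatial normalisation resamples a path at 101 points equally spaced
along its cumulative arc length (0-100% of the movement distance);
temporal normalisation interpolates at 101 equally spaced time points
and is the input convention for sample entropy.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import DegenerateTrialError

N_POINTS = 101


@dataclass
class RawTrajectory:
    """One trial's ordered cursor samples in screen pixels."""

    participant_id: str
    trial_id: str
    t_ms: np.ndarray          # shape (n,), strictly increasing, t[0] == 0
    xy: np.ndarray            # shape (n, 2), screen pixels
    response_side: str        # "left" or "right"

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        if len(self.t_ms) < 2:
            raise DegenerateTrialError(
                "trajectory needs at least 2 samples",
                self.participant_id, self.trial_id)
        if self.t_ms[0] != 0:
            raise DegenerateTrialError(
                "first sample must be at t_ms=0",
                self.participant_id, self.trial_id)

    @property
    def start(self) -> np.ndarray:
        return self.xy[0]

    @property
    def click(self) -> np.ndarray:
        return self.xy[-1]


@dataclass
class NormalizedTrajectory:
    """A resampled path with provenance tags."""

    participant_id: str
    trial_id: str
    xy: np.ndarray            # shape (n_points, 2)
    frame: str                # "pixel" or "unit"
    parameterization: str     # "arc_length", "time" or "none"
    mirrored: bool = False
    response_side: str = ""

    @property
    def n_points(self) -> int:
        return len(self.xy)


def trajectories_from_tables(samples: pd.DataFrame,
                             trials: pd.DataFrame) -> Iterator[RawTrajectory]:
    """Yield one :class:`RawTrajectory` per trial-table row, in trial-table
    order.  Trials without samples are skipped (the validator reports
    them)."""
    index = samples.groupby(["participant_id", "trial_id"],
                            sort=False).indices
    t_all = samples["t_ms"].to_numpy(dtype=float)
    xy_all = samples[["x_px", "y_px"]].to_numpy(dtype=float)
    pids = trials["participant_id"].to_numpy()
    tids = trials["trial_id"].to_numpy()
    sides = trials["response_side"].to_numpy()
    for pid, tid, side in zip(pids, tids, sides):
        rows = index.get((pid, tid))
        if rows is None or len(rows) < 2:
            continue
        yield RawTrajectory(
            participant_id=pid,
            trial_id=tid,
            t_ms=t_all[rows],
            xy=xy_all[rows],
            response_side=side,
        )


def remap_coordinates(traj: RawTrajectory) -> NormalizedTrajectory:
    """Map a raw pixel path into the unit frame.

    The map is affine and anchored per trial at the *observed* start
    (first sample) and click (last sample): start -> (0, 0); click ->
    (-1, 1) for a left response, (1, 1) for a right one.  Each axis is
    scaled independently, so the screen-pixel y axis (downward) is
    flipped in the process.
    """
    start, click = traj.start, traj.click
    dx = click[0] - start[0]
    dy = click[1] - start[1]
    if dx == 0 or dy == 0:
        raise DegenerateTrialError(
            "start and click coincide on one axis; per-trial affine map "
            "is undefined", traj.participant_id, traj.trial_id)
    tx = -1.0 if traj.response_side == "left" else 1.0
    xy = np.empty_like(traj.xy)
    xy[:, 0] = (traj.xy[:, 0] - start[0]) * (tx / dx)
    xy[:, 1] = (traj.xy[:, 1] - start[1]) * (1.0 / dy)
    return NormalizedTrajectory(
        participant_id=traj.participant_id, trial_id=traj.trial_id,
        xy=xy, frame="unit", parameterization="none",
        response_side=traj.response_side)


def mirror_to_right(traj: NormalizedTrajectory) -> NormalizedTrajectory:
    """Reflect left-response paths onto the right so trials can be
    averaged; idempotent."""
    if traj.frame != "unit":
        raise ValueError("mirror_to_right expects a unit-frame trajectory")
    xy = traj.xy
    if xy[-1, 0] < 0:
        xy = xy * np.array([-1.0, 1.0])
    return replace(traj, xy=xy, mirrored=True)


def _as_points(traj) -> np.ndarray:
    return traj.xy if hasattr(traj, "xy") else np.asarray(traj, dtype=float)


def resample_polyline_spatial(points: np.ndarray, n: int = N_POINTS) -> np.ndarray:
    """Resample a polyline at ``n`` points equally spaced along its
    cumulative arc length (linear interpolation; endpoints preserved)."""
    points = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        raise DegenerateTrialError("total path length is zero")
    targets = np.linspace(0.0, total, n)
    out = np.column_stack([
        np.interp(targets, s, points[:, 0]),
        np.interp(targets, s, points[:, 1]),
    ])
    out[0] = points[0]
    out[-1] = points[-1]
    return out


def resample_spatial(traj, n: int = N_POINTS) -> NormalizedTrajectory:
    """Spatially normalise a trajectory to ``n`` (default 101) points
    along 0-100% of the movement distance.

    Accepts a :class:`RawTrajectory` (output frame "pixel") or a
    :class:`NormalizedTrajectory` (frame preserved).
    """
    points = _as_points(traj)
    try:
        xy = resample_polyline_spatial(points, n)
    except DegenerateTrialError as e:
        raise DegenerateTrialError(
            str(e), getattr(traj, "participant_id", ""),
            getattr(traj, "trial_id", "")) from None
    frame = getattr(traj, "frame", "pixel")
    return NormalizedTrajectory(
        participant_id=getattr(traj, "participant_id", ""),
        trial_id=getattr(traj, "trial_id", ""),
        xy=xy, frame=frame, parameterization="arc_length",
        mirrored=getattr(traj, "mirrored", False),
        response_side=getattr(traj, "response_side", ""))


def resample_temporal(traj: RawTrajectory, n: int = N_POINTS) -> NormalizedTrajectory:
    """Interpolate x and y at ``n`` equally spaced times between the
    first and last timestamps."""
    t = np.asarray(traj.t_ms, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise DegenerateTrialError(
            "duplicate or decreasing timestamps",
            traj.participant_id, traj.trial_id)
    targets = np.linspace(t[0], t[-1], n)
    xy = np.column_stack([
        np.interp(targets, t, traj.xy[:, 0]),
        np.interp(targets, t, traj.xy[:, 1]),
    ])
    return NormalizedTrajectory(
        participant_id=traj.participant_id, trial_id=traj.trial_id,
        xy=xy, frame="pixel", parameterization="time",
        response_side=traj.response_side)


def trajectories_frame(trajs: list[NormalizedTrajectory]) -> pd.DataFrame:
    """Long-format export: one row per resampled point."""
    rows = []
    for tr in trajs:
        for i, (x, y) in enumerate(tr.xy):
            rows.append((tr.participant_id, tr.trial_id, i, x, y,
                         tr.frame, tr.parameterization))
    return pd.DataFrame(rows, columns=[
        "participant_id", "trial_id", "point_index", "x", "y",
        "frame", "parameterization"])
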