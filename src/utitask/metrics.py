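"""Trial-level conflict measures: reaction time, signed maximum
absolute deviation (MAD), sample entropy, and condition-average
trajectories.

MAD is the largest perpendicular distance between the observed path and
the straight chord from its first to its last point, and is the field's
workhorse curvature index: larger values indicate stronger competition
between the two response alternatives.  The sign convention here is
that positive MAD means the extreme point lies on the side of the chord
facing the *non-chosen* response box — the direction attributable to
attraction toward the competing alternative.

Sample entropy (SampEn) quantifies the irregularity of a series: the
negative log ratio of (m+1)-length to m-length template matches within
a tolerance r.  It is computed on the x coordinate of the
time-normalised trajectory, where lateral hesitation shows up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateTrialError
from .preprocess import (
    N_POINTS,
    NormalizedTrajectory,
    RawTrajectory,
    mirror_to_right,
    remap_coordinates,
    resample_spatial,
    resample_temporal,
    trajectories_from_tables,
)

METRIC_COLUMNS = ["participant_id", "trial_id", "rt_ms", "mad_px",
                  "mad_unit", "sample_entropy", "degenerate"]


def reaction_time(traj: RawTrajectory) -> float:
    """Milliseconds from movement onset (t=0 by construction) to click."""
    return float(traj.t_ms[-1] - traj.t_ms[0])


def _signed_deviations(points: np.ndarray) -> np.ndarray:
    """Perpendicular point-to-line distances from each point to the
    chord through the first and last points, signed by side (positive =
    counterclockwise side of the chord vector)."""
    p0, p1 = points[0], points[-1]
    chord = p1 - p0
    norm = np.hypot(*chord)
    if norm == 0:
        raise DegenerateTrialError("chord has zero length")
    rel = points - p0
    cross = chord[0] * rel[:, 1] - chord[1] * rel[:, 0]
    return cross / norm


def mad_signed(traj, sign_reference: np.ndarray | None = None) -> float:
    """Signed maximum absolute deviation from the start-to-end chord.

    Parameters
    ----------
    traj
        A :class:`NormalizedTrajectory` (arc-length parameterised) or a
        plain (n, 2) point array.
    sign_reference
        A point marking the side of the chord to be counted positive
        (the non-chosen response box).  Defaults to the reflection of
        the endpoint across the vertical line through the start, which
        is the competing box's side in both the pixel and unit frames.

    Returns the deviation of largest magnitude, positive when the
    extreme point lies on the ``sign_reference`` side of the chord.
    """
    points = traj.xy if hasattr(traj, "xy") else np.asarray(traj, dtype=float)
    dev = _signed_deviations(points)
    i = int(np.argmax(np.abs(dev)))
    if sign_reference is None:
        p0, p1 = points[0], points[-1]
        sign_reference = np.array([2.0 * p0[0] - p1[0], p1[1]])
    ref_side = _signed_deviations(
        np.vstack([points[0], sign_reference, points[-1]]))[1]
    orient = 1.0 if ref_side >= 0 else -1.0
    return float(dev[i] * orient)


def sample_entropy(series, m: int = 2, r_frac: float = 0.2,
                   with_flag: bool = False):
    """Sample entropy of a 1-D series.

    SampEn = -ln(A/B), where B counts pairs of length-``m`` templates
    whose Chebyshev distance is <= r, A the same for length ``m+1``;
    self-matches are excluded and r = ``r_frac`` x SD(series).
    Degenerate cases (zero SD, or no matches at either length) return
    0 by convention, flagged when ``with_flag`` is set.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < m + 2:
        raise ValueError(f"series of length {n} too short for m={m}")
    sd = float(np.std(x))
    if sd == 0:
        return (0.0, True) if with_flag else 0.0
    r = r_frac * sd
    # within-tolerance indicator for scalar pairs; a length-mm template
    # pair matches iff all mm diagonal-shifted entries match
    close = np.abs(x[:, None] - x[None, :]) <= r

    def count_matches(mm: int) -> int:
        k = n - mm + 1
        match = close[:k, :k].copy()
        for shift in range(1, mm):
            match &= close[shift:shift + k, shift:shift + k]
        return int(np.triu(match, 1).sum())

    b = count_matches(m)
    a = count_matches(m + 1)
    if a == 0 or b == 0:
        return (0.0, True) if with_flag else 0.0
    value = float(-np.log(a / b))
    return (value, False) if with_flag else value


@dataclass
class AverageTrajectory:
    """Pointwise mean of a set of unit-frame, mirrored, arc-length
    normalised trajectories."""

    label: str
    xy: np.ndarray            # (101, 2)
    n_trials: int


def average_trajectory(trajs: list[NormalizedTrajectory],
                       label: str = "") -> AverageTrajectory:
    if not trajs:
        raise ValueError("cannot average an empty trajectory list")
    for tr in trajs:
        if tr.frame != "unit" or not tr.mirrored \
                or tr.parameterization != "arc_length" \
                or tr.n_points != N_POINTS:
            raise ValueError(
                "average_trajectory expects unit-frame, mirrored, "
                f"arc-length {N_POINTS}-point trajectories")
    stack = np.stack([tr.xy for tr in trajs])
    return AverageTrajectory(label=label, xy=stack.mean(axis=0),
                             n_trials=len(trajs))


def compute_trial_metrics(samples: pd.DataFrame, trials: pd.DataFrame,
                          include_sample_entropy: bool = True,
                          sampen_m: int = 2,
                          sampen_r_frac: float = 0.2) -> pd.DataFrame:
    """Run the per-trial metric pipeline over a dataset.

    Returns one row per trial with ``rt_ms``, ``mad_px`` (pixel frame),
    ``mad_unit`` (unit frame), ``sample_entropy`` and a ``degenerate``
    flag.  Degenerate trials (zero extent or path length) keep their
    row with NaN metrics so exclusion reports can audit them.
    """
    rows = []
    for raw in trajectories_from_tables(samples, trials):
        rt = reaction_time(raw)
        try:
            unit = mirror_to_right(remap_coordinates(raw))
            unit_arc = resample_spatial(unit)
            px_arc = resample_spatial(raw)
            m_px = mad_signed(px_arc)
            m_unit = mad_signed(unit_arc, sign_reference=np.array([-1.0, 1.0]))
            if include_sample_entropy:
                tnorm = resample_temporal(raw)
                se = sample_entropy(tnorm.xy[:, 0], m=sampen_m,
                                    r_frac=sampen_r_frac)
            else:
                se = np.nan
            rows.append((raw.participant_id, raw.trial_id, rt,
                         m_px, m_unit, se, False))
        except DegenerateTrialError:
            rows.append((raw.participant_id, raw.trial_id, rt,
                         np.nan, np.nan, np.nan, True))
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)
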