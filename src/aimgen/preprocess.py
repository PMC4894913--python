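"""From raw trial tables to analysis quantities.

Converts reported landmarks to aiming angles, decomposes each reach into its
explicit (reported aim) and implicit (reach minus aim) components, bins
series for display/analysis, and computes plateau values over the final
rotation trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .protocol import LANDMARK_SPACING_DEG


class IncompleteTrialError(ValueError):
    """Movement trajectory never crossed the target radius."""


def landmark_to_angle(landmark) -> float:
    """Aiming angle (deg, CCW positive) of a reported landmark number.

    The ring is numbered so that CCW aims have negative landmark numbers;
    the conversion is ``landmark * -5.625``.  Non-integer input is rejected;
    a missing report (None/NaN) propagates as NaN.
    """
    if landmark is None or landmark is pd.NA:
        return math.nan
    if isinstance(landmark, float):
        if math.isnan(landmark):
            return math.nan
        if not landmark.is_integer():
            raise ValueError(f"reported landmark must be an integer, got {landmark}")
        landmark = int(landmark)
    if not isinstance(landmark, (int, np.integer)):
        raise ValueError(f"reported landmark must be an integer, got {landmark!r}")
    return float(landmark) * -LANDMARK_SPACING_DEG


def reach_angle_from_trajectory(samples, radius: float = 70.0) -> float:
    """Reach angle at the first crossing of the target radius.

    ``samples`` are ordered planar positions in mm (x rightward, y toward the
    target); the reach angle is measured relative to straight-ahead (+y),
    CCW positive.  The crossing angle is linearly interpolated in radius
    between the two samples bracketing ``radius``.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    pts = np.asarray(samples, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) == 0:
        raise ValueError("samples must be a non-empty (n, 2) array of planar points")
    r = np.hypot(pts[:, 0], pts[:, 1])
    angles = np.degrees(np.arctan2(-pts[:, 0], pts[:, 1]))
    beyond = np.nonzero(r >= radius)[0]
    if len(beyond) == 0:
        raise IncompleteTrialError(
            f"trajectory never reached the {radius} mm target distance "
            f"(max excursion {r.max():.1f} mm)"
        )
    j = int(beyond[0])
    if j == 0 or r[j] == radius:
        return float(angles[j])
    i = j - 1
    t = (radius - r[i]) / (r[j] - r[i])
    return float(angles[i] + t * (angles[j] - angles[i]))


def calculated_implicit(reach_angle, aim_angle):
    """Implicit component of one reach: reach minus reported aim (degrees).

    A missing aim report propagates as NaN rather than zero.
    """
    return np.asarray(reach_angle, dtype=float) - np.asarray(aim_angle, dtype=float)


def bin_series(values, bin_size: int = 4) -> np.ndarray:
    """Means over consecutive non-overlapping bins of ``bin_size`` trials.

    A trailing partial bin is averaged over its available trials; NaNs are
    excluded from bin means (an all-NaN bin yields NaN).
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) == 0:
        raise ValueError("bin_series requires a non-empty 1-d series")
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    out = []
    for start in range(0, len(v), bin_size):
        chunk = v[start : start + bin_size]
        good = chunk[~np.isnan(chunk)]
        out.append(good.mean() if len(good) else math.nan)
    return np.asarray(out)


def plateau(values, last_n: int = 100) -> float:
    """Mean over the final ``last_n`` trials of a series, NaNs excluded."""
    v = np.asarray(values, dtype=float)
    if len(v) < last_n:
        raise ValueError(
            f"series has {len(v)} trials, {last_n - len(v)} fewer than the "
            f"{last_n} required for the plateau window"
        )
    tail = v[-last_n:]
    good = tail[~np.isnan(tail)]
    return float(good.mean()) if len(good) else math.nan


@dataclass
class SubjectSeries:
    """Per-trial rotation-block series plus catch probes for one subject."""

    subject_id: str
    group_name: str
    reach_angle: np.ndarray
    aim_angle: np.ndarray
    calculated_implicit: np.ndarray
    reported_landmark: np.ndarray  # float array; NaN where absent
    catch_magnitude: np.ndarray  # reach minus probe direction, per catch
    catch_direction: float
    probe_trials: np.ndarray  # 1-based rotation-trial index preceding each probe
    aftereffect_magnitude: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.reach_angle)
        for name in ("aim_angle", "calculated_implicit", "reported_landmark"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length differs from reach_angle")


def subject_series(trials: pd.DataFrame) -> SubjectSeries:
    """Extract a :class:`SubjectSeries` from one subject's trial rows.

    Rows must be in temporal order within blocks.  Each catch probe is
    anchored to the rotation trial immediately preceding it in the table, so
    the 4-trial pre-probe bins used by the phi statistic never straddle a
    probe regardless of where the protocol placed it.
    """
    sid = trials["subject_id"].iloc[0]
    group = trials["group_name"].iloc[0]
    rot = trials[trials["block_label"] == "rotation"].sort_values("trial_index")
    if len(rot) == 0:
        raise ValueError(f"subject {sid}: no rotation-block trials")
    reach = rot["reach_angle"].to_numpy(dtype=float)
    lm = rot["reported_landmark"].to_numpy(dtype=float, na_value=math.nan)
    aim = lm * -LANDMARK_SPACING_DEG
    implicit = calculated_implicit(reach, aim)

    catch = trials[trials["block_label"] == "catch"].sort_values("trial_index")
    catch_mag = (
        catch["reach_angle"].to_numpy(dtype=float)
        - catch["target_direction"].to_numpy(dtype=float)
    )
    catch_dir = float(catch["target_direction"].iloc[0]) if len(catch) else math.nan

    # anchor each probe at the last rotation trial appearing before it
    labels = trials["block_label"].to_numpy()
    tidx = trials["trial_index"].to_numpy(dtype=int)
    running = np.maximum.accumulate(np.where(labels == "rotation", tidx, 0))
    probe_anchor = running[labels == "catch"]

    after = trials[trials["block_label"] == "aftereffect"].sort_values("trial_index")
    after_mag = (
        after["reach_angle"].to_numpy(dtype=float)
        - after["target_direction"].to_numpy(dtype=float)
    )

    return SubjectSeries(
        subject_id=sid,
        group_name=group,
        reach_angle=reach,
        aim_angle=aim,
        calculated_implicit=implicit,
        reported_landmark=lm,
        catch_magnitude=catch_mag,
        catch_direction=catch_dir,
        probe_trials=np.asarray(probe_anchor, dtype=int),
        aftereffect_magnitude=after_mag,
    )


def cohort_series(trials: pd.DataFrame) -> dict[str, SubjectSeries]:
    """Split a cohort trial table into per-subject series, keyed by subject."""
    return {
        sid: subject_series(sub)
        for sid, sub in trials.groupby("subject_id", sort=False)
    }
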