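"""Experiment protocol: blocks, probe placement, and group-specific probe directions.

The experiment is a center-out reaching task under a 45 degree clockwise
visuomotor rotation.  Angles are in degrees, counterclockwise (CCW) positive,
with 0 at the trained target; the CW rotation is therefore stored as -45.
Aiming landmarks form a ring of consecutively numbered points spaced 5.625
degrees apart, with landmark 0 at the target and landmark angle equal to
``landmark * -5.625`` (CCW reaches map to negative landmark numbers).

Each group runs the same five blocks -- 48 baseline trials, 8 baseline trials
with aim reports, 320 rotation trials with aim reports, 40 no-feedback
aftereffect trials, and 40 washout trials -- and differs only in where the
no-feedback catch probes and the aftereffect trials are placed relative to the
trained target.  Seven single catch trials are inserted into the rotation
block, one after every 40th rotation trial (trials 40, 80, ..., 280).
"""

from __future__ import annotations

from dataclasses import dataclass, field

LANDMARK_SPACING_DEG = 5.625
#: landmark numbers form a ring covering 360 degrees
LANDMARK_MIN, LANDMARK_MAX = -32, 31

ROTATION_DEG = -45.0

N_BASELINE = 48
N_BASELINE_REPORT = 8
N_ROTATION = 320
N_AFTEREFFECT = 40
N_WASHOUT = 40

N_CATCH = 7
CATCH_EVERY = 40

#: group name -> (catch probe direction, aftereffect direction), degrees CCW+
GROUP_PROBE_DIRECTIONS: dict[str, tuple[float, float]] = {
    "target": (0.0, 0.0),
    "aim": (30.0, 30.0),
    "extreme_ccw": (60.0, 60.0),
    "extreme_cw": (-90.0, -90.0),
    "cursor": (-30.0, -30.0),
    "hand": (45.0, 45.0),
    "aim_target": (30.0, 0.0),
}

GROUPS = tuple(GROUP_PROBE_DIRECTIONS)

BLOCK_LABELS = (
    "baseline",
    "baseline_report",
    "rotation",
    "catch",
    "aftereffect",
    "washout",
)


def landmark_angle(landmark: int) -> float:
    """Angle (deg, CCW positive) of a numbered aiming landmark."""
    return landmark * -LANDMARK_SPACING_DEG


def nearest_landmark(angle_deg: float) -> int:
    """Landmark number whose ring position is closest to ``angle_deg``."""
    return int(round(angle_deg / -LANDMARK_SPACING_DEG))


def wrap_angle(angle_deg: float) -> float:
    """Normalize an angle into (-180, 180]."""
    a = (angle_deg + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


@dataclass(frozen=True)
class ProtocolSchedule:
    """Ordered trial plan for one experimental group.

    ``probe_trials`` are 1-based rotation-trial indices after which a single
    no-feedback catch probe is inserted; the 320 rotation trials are counted
    excluding the probes themselves.
    """

    group_name: str
    catch_direction: float
    aftereffect_direction: float
    rotation_deg: float = ROTATION_DEG
    block_sequence: tuple[tuple[str, int], ...] = (
        ("baseline", N_BASELINE),
        ("baseline_report", N_BASELINE_REPORT),
        ("rotation", N_ROTATION),
        ("aftereffect", N_AFTEREFFECT),
        ("washout", N_WASHOUT),
    )
    probe_trials: tuple[int, ...] = field(
        default=tuple(CATCH_EVERY * (i + 1) for i in range(N_CATCH))
    )

    @property
    def n_learning_trials(self) -> int:
        return sum(n for _, n in self.block_sequence)

    @property
    def n_total_trials(self) -> int:
        return self.n_learning_trials + len(self.probe_trials)


def make_protocol(group_name: str) -> ProtocolSchedule:
    """Build the schedule for one of the seven experimental groups.

    Raises
    ------
    ValueError
        If ``group_name`` is not a known group; the message lists valid names.
    """
    try:
        catch_dir, after_dir = GROUP_PROBE_DIRECTIONS[group_name]
    except KeyError:
        raise ValueError(
            f"unknown group {group_name!r}; valid groups: {', '.join(GROUPS)}"
        ) from None
    return ProtocolSchedule(
        group_name=group_name,
        catch_direction=catch_dir,
        aftereffect_direction=after_dir,
    )
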