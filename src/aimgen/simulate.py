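"""Synthetic cohort simulator for the seven-group visuomotor rotation study.

The generative learner is deliberately simple: it exists so the analysis
pipeline (implicit/explicit decomposition, catch-trial phi, generalization
curves) has data with the right statistical structure, not as a model of any
particular participant.  Each simulated subject carries

* an *implicit field*: a scalar amplitude expressed through a Gaussian tuning
  kernel ``K(d) = exp(-d^2 / (2 w^2))`` centered on ``kernel_center``, so the
  implicit contribution at a movement direction ``theta`` is
  ``amplitude * K(theta - kernel_center)``;
* an *explicit aiming policy*: a discrete landmark the subject aims at, which
  re-aims on feedback trials by whole landmarks toward reducing target error.

On every feedback trial the amplitude follows a single-rate state-space
update, ``amplitude <- A * amplitude - B * SPE``, where the sensory
prediction error ``SPE = cursor_angle - aim_angle`` (negative under the CW
rotation, so learning accrues CCW), and the kernel center relaxes toward the
current aim direction with rate ``center_rate``.  Catch, aftereffect, and
washout trials force the aim to the displayed probe target, as instructed in
the task, so no-feedback probe reaches read out the implicit field directly.

Reach angles are degrees, CCW positive, 0 at the trained target.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .protocol import (
    GROUPS,
    LANDMARK_SPACING_DEG,
    ProtocolSchedule,
    landmark_angle,
    make_protocol,
)

TRIAL_COLUMNS = (
    "subject_id",
    "group_name",
    "block_label",
    "trial_index",
    "target_direction",
    "reach_angle",
    "reported_landmark",
    "cursor_angle",
)


@dataclass(frozen=True)
class LearnerState:
    """Implicit field plus current aiming policy of one simulated subject."""

    implicit_amplitude: float = 0.0
    kernel_center: float = 0.0
    kernel_width: float = 35.0
    aim_landmark: int = 0
    retention_a: float = 0.98
    learning_rate_b: float = 0.0133
    center_rate: float = 0.1
    p_reaim: float = 0.2
    reaim_cap: int = 2

    def __post_init__(self) -> None:
        if not (0.0 < self.retention_a <= 1.0):
            raise ValueError(f"retention A must be in (0, 1], got {self.retention_a}")
        if not (0.0 <= self.learning_rate_b < 1.0):
            raise ValueError(
                f"learning rate B must be in [0, 1), got {self.learning_rate_b}"
            )
        if self.kernel_width <= 0:
            raise ValueError("kernel width must be positive")

    def kernel(self, delta_deg: float) -> float:
        """Gaussian tuning kernel; K(0)=1 and K symmetric."""
        if math.isinf(self.kernel_width):
            return 1.0
        return math.exp(-(delta_deg**2) / (2.0 * self.kernel_width**2))

    def implicit_at(self, theta_deg: float) -> float:
        """Implicit contribution expressed at movement direction ``theta``."""
        return self.implicit_amplitude * self.kernel(theta_deg - self.kernel_center)


@dataclass(frozen=True)
class TrialContext:
    """Everything a single trial needs besides the learner state."""

    block_label: str
    trial_index: int
    target_direction: float = 0.0
    rotation_deg: float = 0.0
    feedback: bool = True
    report: bool = False
    forced_aim: float | None = None  # instructed aim (catch/aftereffect/washout)


@dataclass(frozen=True)
class TrialDraws:
    """Random draws consumed by one trial (supplied by the caller)."""

    motor_noise: float = 0.0
    u_reaim: float = 1.0  # uniform in [0,1); re-aim fires when < p_reaim


def step_learner(
    state: LearnerState, ctx: TrialContext, draws: TrialDraws
) -> tuple[LearnerState, dict]:
    """Simulate one trial; pure function of ``(state, ctx, draws)``.

    Returns the post-trial state and a trial record dict (one CSV row).
    Absent values (no report, no feedback) are ``None``.
    """
    if ctx.forced_aim is not None:
        aim_angle = ctx.forced_aim
    else:
        aim_angle = landmark_angle(state.aim_landmark)

    reach = aim_angle + state.implicit_at(aim_angle) + draws.motor_noise
    cursor = reach + ctx.rotation_deg if ctx.feedback else None

    record = {
        "block_label": ctx.block_label,
        "trial_index": ctx.trial_index,
        "target_direction": ctx.target_direction,
        "reach_angle": reach,
        "reported_landmark": state.aim_landmark if ctx.report else None,
        "cursor_angle": cursor,
    }

    if not ctx.feedback:
        return state, record

    spe = cursor - aim_angle
    new_amplitude = state.retention_a * state.implicit_amplitude - state.learning_rate_b * spe
    new_center = state.kernel_center + state.center_rate * (aim_angle - state.kernel_center)

    new_landmark = state.aim_landmark
    if ctx.forced_aim is None and draws.u_reaim < state.p_reaim:
        target_error = cursor - ctx.target_direction
        shift = int(round(target_error / LANDMARK_SPACING_DEG))
        shift = max(-state.reaim_cap, min(state.reaim_cap, shift))
        new_landmark = state.aim_landmark + shift

    new_state = replace(
        state,
        implicit_amplitude=new_amplitude,
        kernel_center=new_center,
        aim_landmark=new_landmark,
    )
    return new_state, record


@dataclass(frozen=True)
class CohortConfig:
    """Population-level simulation parameters.

    Per-subject learning rate and kernel width are drawn from truncated
    normal distributions so subjects differ in plateau implicit amplitude
    (about 15-20 deg under the defaults) and in generalization width.
    """

    n_subjects_per_group: int = 10
    groups: tuple[str, ...] = GROUPS
    retention_a: float = 0.98
    learning_rate_b_mean: float = 0.0133
    learning_rate_b_sd: float = 0.003
    learning_rate_b_min: float = 0.004
    kernel_width_mean: float = 35.0
    kernel_width_sd: float = 5.0
    kernel_width_min: float = 15.0
    center_rate: float = 0.1
    motor_noise_sd: float = 3.0
    p_reaim: float = 0.2
    reaim_cap: int = 2
    initial_amplitude: float = 0.0

    def __post_init__(self) -> None:
        if self.n_subjects_per_group < 1:
            raise ValueError("n_subjects_per_group must be >= 1")
        for name in ("learning_rate_b_sd", "kernel_width_sd", "motor_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative, got {getattr(self, name)}")
        unknown = set(self.groups) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown groups: {sorted(unknown)}")


def subject_seed_sequence(master_seed: int, group: str, subject_index: int) -> np.random.SeedSequence:
    """Stable per-subject substream: hash of (seed, group, index).

    Hash-derived so adding or removing a group never perturbs the draws of
    other groups' subjects.
    """
    digest = hashlib.sha256(f"{master_seed}|{group}|{subject_index}".encode()).digest()
    return np.random.SeedSequence(int.from_bytes(digest[:16], "little"))


def _draw_subject_state(cfg: CohortConfig, rng: np.random.Generator) -> LearnerState:
    b = max(cfg.learning_rate_b_min, rng.normal(cfg.learning_rate_b_mean, cfg.learning_rate_b_sd))
    w = max(cfg.kernel_width_min, rng.normal(cfg.kernel_width_mean, cfg.kernel_width_sd))
    return LearnerState(
        implicit_amplitude=cfg.initial_amplitude,
        kernel_center=0.0,
        kernel_width=w,
        aim_landmark=0,
        retention_a=cfg.retention_a,
        learning_rate_b=b,
        center_rate=cfg.center_rate,
        p_reaim=cfg.p_reaim,
        reaim_cap=cfg.reaim_cap,
    )


def _iter_trial_contexts(protocol: ProtocolSchedule) -> Iterable[TrialContext]:
    """Temporal order of trials for one subject, probes inserted."""
    for i in range(1, protocol.block_sequence[0][1] + 1):
        yield TrialContext("baseline", i)
    for i in range(1, protocol.block_sequence[1][1] + 1):
        yield TrialContext("baseline_report", i, report=True)
    catch_i = 0
    for i in range(1, protocol.block_sequence[2][1] + 1):
        yield TrialContext(
            "rotation", i, rotation_deg=protocol.rotation_deg, report=True
        )
        if catch_i < len(protocol.probe_trials) and i == protocol.probe_trials[catch_i]:
            catch_i += 1
            yield TrialContext(
                "catch",
                catch_i,
                target_direction=protocol.catch_direction,
                feedback=False,
                forced_aim=protocol.catch_direction,
            )
    for i in range(1, protocol.block_sequence[3][1] + 1):
        yield TrialContext(
            "aftereffect",
            i,
            target_direction=protocol.aftereffect_direction,
            feedback=False,
            forced_aim=protocol.aftereffect_direction,
        )
    for i in range(1, protocol.block_sequence[4][1] + 1):
        yield TrialContext("washout", i, forced_aim=0.0)


def simulate_subject(
    subject_id: str,
    protocol: ProtocolSchedule,
    state: LearnerState,
    rng: np.random.Generator,
    motor_noise_sd: float = 3.0,
    trace: bool = False,
) -> list[dict] | tuple[list[dict], list[dict]]:
    """Run one subject through the full protocol.

    With ``trace=True`` also returns the pre-trial learner state per trial
    (amplitude, kernel center, aim angle) for oracle-style checks.
    """
    contexts = list(_iter_trial_contexts(protocol))
    n = len(contexts)
    noise = rng.normal(0.0, motor_noise_sd, size=n) if motor_noise_sd > 0 else np.zeros(n)
    u = rng.random(size=n)
    rows: list[dict] = []
    states: list[dict] = []
    for k, ctx in enumerate(contexts):
        if trace:
            states.append(
                {
                    "block_label": ctx.block_label,
                    "trial_index": ctx.trial_index,
                    "implicit_amplitude": state.implicit_amplitude,
                    "kernel_center": state.kernel_center,
                    "kernel_width": state.kernel_width,
                    "aim_landmark": state.aim_landmark,
                }
            )
        state, record = step_learner(
            state, ctx, TrialDraws(motor_noise=float(noise[k]), u_reaim=float(u[k]))
        )
        record["subject_id"] = subject_id
        record["group_name"] = protocol.group_name
        rows.append(record)
    if trace:
        return rows, states
    return rows


def simulate_cohort(
    config: CohortConfig | None = None, seed: int = 0
) -> pd.DataFrame:
    """Simulate the full multi-group cohort as one tidy trial table.

    Deterministic under a fixed ``seed``; rows are in temporal order within
    each subject.  Absent values (no feedback, no report) are NaN/NA.
    """
    cfg = config or CohortConfig()
    all_rows: list[dict] = []
    for group in cfg.groups:
        protocol = make_protocol(group)
        for idx in range(1, cfg.n_subjects_per_group + 1):
            rng = np.random.default_rng(subject_seed_sequence(seed, group, idx))
            state = _draw_subject_state(cfg, rng)
            subject_id = f"{group}_{idx:02d}"
            all_rows.extend(
                simulate_subject(
                    subject_id, protocol, state, rng, motor_noise_sd=cfg.motor_noise_sd
                )
            )
    df = pd.DataFrame(all_rows, columns=list(TRIAL_COLUMNS))
    df["reported_landmark"] = df["reported_landmark"].astype("Int64")
    for col in ("target_direction", "reach_angle", "cursor_angle"):
        df[col] = df[col].astype(float)
    return df
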