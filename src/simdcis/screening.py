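"""Screening overlay on latent trajectories.

A policy defines invitation rounds; attendance is drawn per woman (either
independently per round or once for all rounds); an attended mammogram
detects a prevalent, still-undetected DCIS episode with the per-screen
sensitivity.  The overlay never mutates the latent trajectory: the
screened arm's outcome is the first successful screen detection, or —
failing that — the trajectory's own clinical/progression diagnosis.

Timing convention (fixed, mirrored exactly by the Markov oracle): a screen
at age ``a`` precedes the DCIS-state events of cycle ``a`` and follows the
onset event of cycle ``a``.  It therefore observes any episode with
``onset_age <= a`` that has not resolved strictly before ``a``
(``resolution_age >= a`` or unresolved), and a same-age tie between screen
detection and clinical detection/progression resolves in favour of the
screen.  A woman is alive at the screen iff her death age is ``>= a``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import N_ROUND_SLOTS, RandomStream, uniform_block
from .natural_history import (
    RES_CLINICAL,
    RES_IBC,
    CohortArrays,
    LatentTrajectory,
)
from .parameters import ScreeningPolicy

DX_NONE = "none"
DX_SCREEN = "screen_detected_dcis"
DX_CLINICAL = "clinically_detected_dcis"
DX_IBC = "dcis_progressed_to_ibc"
_LATENT_DX = {RES_CLINICAL: DX_CLINICAL, RES_IBC: DX_IBC}


@dataclass(frozen=True)
class ScreenRound:
    round_index: int
    age: int


@dataclass(frozen=True)
class AttendanceRecord:
    woman_id: int
    attended: tuple[bool, ...]

    @property
    def attended_any(self) -> bool:
        return any(self.attended)


@dataclass(frozen=True)
class ArmOutcome:
    """Diagnosis (if any) observed in one arm for one woman."""

    diagnosis: str = DX_NONE
    diagnosis_age: int | None = None
    grade: int | None = None
    attended_any: bool = False

    def __post_init__(self) -> None:
        if (self.diagnosis == DX_NONE) != (self.diagnosis_age is None):
            raise ValueError("diagnosis_age must be present iff diagnosed")
        if (self.diagnosis == DX_NONE) != (self.grade is None):
            raise ValueError("grade must be present iff diagnosed")


def build_schedule(policy: ScreeningPolicy) -> list[ScreenRound]:
    """Invitation rounds at start_age, start_age+interval, ... <= stop_age."""
    return [ScreenRound(j, a) for j, a in enumerate(policy.round_ages())]


def draw_attendance(
    policy: ScreeningPolicy, schedule: list[ScreenRound], stream: RandomStream
) -> AttendanceRecord:
    """Draw one woman's attendance; round j consumes deviate j of the stream."""
    if stream.purpose != "attendance":
        raise ValueError(f"stream purpose must be attendance, got {stream.purpose!r}")
    u = stream.generator().random(N_ROUND_SLOTS)[: len(schedule)]
    if policy.attendance_model == "all_or_none":
        goes = bool(u[0] < policy.compliance) if len(schedule) else False
        attended = (goes,) * len(schedule)
    else:
        attended = tuple(bool(x) for x in (u < policy.compliance))
    return AttendanceRecord(woman_id=stream.woman_id, attended=attended)


def unscreened_outcome(traj: LatentTrajectory) -> ArmOutcome:
    """The trajectory's own terminal diagnosis, if any (attendance: none)."""
    if traj.episodes:
        last = traj.episodes[-1]
        if last.resolution in ("clinically_detected", "progressed_to_ibc"):
            dx = DX_CLINICAL if last.resolution == "clinically_detected" else DX_IBC
            return ArmOutcome(dx, last.resolution_age, last.grade, attended_any=False)
    return ArmOutcome()


def _active_episode(traj: LatentTrajectory, age: int):
    for ep in traj.episodes:
        if ep.onset_age <= age and (ep.resolution_age is None or ep.resolution_age >= age):
            return ep
    return None


def apply_screening(
    traj: LatentTrajectory,
    schedule: list[ScreenRound],
    attendance: AttendanceRecord,
    sensitivity: float,
    stream: RandomStream,
) -> ArmOutcome:
    """Screened-arm outcome for one woman; the trajectory is not mutated.

    The sensitivity draw for round j consumes deviate j of the screen_test
    stream unconditionally, so outcomes couple across policies sharing a
    seed (common random numbers by round index).
    """
    if stream.purpose != "screen_test":
        raise ValueError(f"stream purpose must be screen_test, got {stream.purpose!r}")
    if attendance.woman_id != stream.woman_id:
        raise ValueError(
            f"attendance woman_id {attendance.woman_id} != stream woman_id {stream.woman_id}"
        )
    if len(attendance.attended) != len(schedule):
        raise ValueError("attendance record length does not match schedule")
    u = stream.generator().random(N_ROUND_SLOTS)
    attended_any = attendance.attended_any
    for rnd in schedule:
        a = rnd.age
        if not attendance.attended[rnd.round_index]:
            continue
        if traj.death_age is not None and traj.death_age < a:
            break
        ep = _active_episode(traj, a)
        if ep is not None and u[rnd.round_index] < sensitivity:
            return ArmOutcome(DX_SCREEN, a, ep.grade, attended_any=attended_any)
    base = unscreened_outcome(traj)
    return ArmOutcome(base.diagnosis, base.diagnosis_age, base.grade, attended_any=attended_any)


# ---------------------------------------------------------------------------
# Vectorised cohort overlay
# ---------------------------------------------------------------------------


@dataclass
class ScreenedArm:
    """Cohort-level screened-arm outcome in column form.

    ``dx_age < 0`` means no diagnosis; ``screen_detected`` marks which
    diagnoses came from a screen (others inherit the latent diagnosis).
    ``n_screens`` counts screens actually performed per woman: rounds she
    attended while alive and not yet diagnosed in this arm — the default
    denominator of the overdiagnosis rate.
    """

    screen_detected: np.ndarray
    dx_code_latent: np.ndarray  # latent code for inherited diagnoses
    dx_age: np.ndarray
    dx_grade: np.ndarray
    attended_any: np.ndarray
    n_screens: np.ndarray


def apply_screening_cohort(
    cohort: CohortArrays,
    policy: ScreeningPolicy,
    sensitivity: float,
    att_uniforms: np.ndarray,
    test_uniforms: np.ndarray,
) -> ScreenedArm:
    """Vectorised :func:`apply_screening` over a whole cohort.

    ``att_uniforms`` / ``test_uniforms`` are ``(n, >=n_rounds)`` matrices
    whose column j is each woman's deviate for round j (from her
    attendance / screen_test stream), so results agree woman-by-woman
    with the per-trajectory code path.
    """
    n = cohort.cohort_size
    ages = policy.round_ages()
    n_rounds = len(ages)
    if att_uniforms.shape[1] < n_rounds or test_uniforms.shape[1] < n_rounds:
        raise ValueError(f"need >= {n_rounds} uniform columns per woman")

    if policy.attendance_model == "all_or_none":
        attend = np.repeat(att_uniforms[:, :1] < policy.compliance, n_rounds, axis=1)
    else:
        attend = att_uniforms[:, :n_rounds] < policy.compliance

    detected = np.zeros(n, dtype=bool)
    screen_age = np.full(n, -1, dtype=np.int16)
    screen_grade = np.zeros(n, dtype=np.int8)
    active_grade = np.zeros(n, dtype=np.int8)
    n_screens = np.zeros(n, dtype=np.int16)
    death = cohort.death_age
    for j, a in enumerate(ages):
        active_grade[:] = 0
        ep = (cohort.ep_onset_age <= a) & (
            (cohort.ep_res_age < 0) | (cohort.ep_res_age >= a)
        )
        active_grade[cohort.ep_woman[ep]] = cohort.ep_grade[ep]
        has_active = active_grade > 0
        # a woman in the DCIS state at cycle start dies after the screen,
        # a healthy woman before it (same tie convention as the oracle)
        alive = np.where(
            has_active, (death < 0) | (death >= a), (death < 0) | (death > a)
        )
        not_dx = ~detected & ((cohort.dx_age < 0) | (cohort.dx_age >= a))
        performed = attend[:, j] & alive & not_dx
        n_screens += performed
        hit = performed & has_active & (test_uniforms[:, j] < sensitivity)
        screen_age[hit] = a
        screen_grade[hit] = active_grade[hit]
        detected |= hit

    dx_age = np.where(detected, screen_age, cohort.dx_age)
    dx_grade = np.where(detected, screen_grade, cohort.dx_grade)
    return ScreenedArm(
        screen_detected=detected,
        dx_code_latent=cohort.dx_code,
        dx_age=dx_age.astype(np.int16),
        dx_grade=dx_grade.astype(np.int8),
        attended_any=n_screens > 0,
        n_screens=n_screens,
    )


def cohort_round_uniforms(cohort_seed: int, cohort_size: int) -> tuple[np.ndarray, np.ndarray]:
    """(attendance, screen_test) uniform matrices for a whole cohort."""
    ids = np.arange(cohort_size)
    att = uniform_block(cohort_seed, ids, "attendance", (N_ROUND_SLOTS,))
    test = uniform_block(cohort_seed, ids, "screen_test", (N_ROUND_SLOTS,))
    return att, test
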