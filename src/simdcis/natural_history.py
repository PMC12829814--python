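"""Screening-independent latent life courses.

Each woman is followed from birth through annual cycles up to ``max_age``.
In the healthy state a cycle resolves death, then DCIS onset (grade chosen
by partitioning one uniform by the grade-specific onset probabilities).
In the DCIS state a cycle resolves death, then progression to invasive
cancer, then clinical detection, then regression, by sequential Bernoulli
draws in that fixed order, one uniform per potential event per cycle,
indexed by (age, event slot).  Progression to invasive cancer and clinical
detection are absorbing diagnoses; death is absorbing; regression returns
the woman to the healthy state, where (by default) later onsets may occur.

The trajectory never references screening.  Screening is a pure
observation overlay applied later (see :mod:`simdcis.screening`), so the
same latent trajectory backs both the screened and the unscreened arm of
the paired design — the common-random-numbers coupling is exact by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import N_CYCLE_SLOTS, RandomStream, uniform_block
from .parameters import GRADES, ModelParameters, require_valid

# Resolution codes used in the array representation.
RES_UNRESOLVED = 0
RES_IBC = 1
RES_CLINICAL = 2
RES_REGRESSED = 3
RESOLUTION_NAMES = {
    RES_UNRESOLVED: "unresolved_at_end",
    RES_IBC: "progressed_to_ibc",
    RES_CLINICAL: "clinically_detected",
    RES_REGRESSED: "regressed",
}

# Internal state codes for the cycle loop.
_HEALTHY = 0  # grades occupy 1..3
_DEAD = 4
_DIAGNOSED = 5  # latent absorbing diagnosis (clinical or progression)
_HEALTHY_NO_REONSET = 6


@dataclass(frozen=True)
class DcisEpisode:
    onset_age: int
    grade: int
    resolution: str
    resolution_age: int | None


@dataclass(frozen=True)
class LatentTrajectory:
    woman_id: int
    death_age: int | None
    episodes: tuple[DcisEpisode, ...]


@dataclass
class CohortArrays:
    """Column-oriented cohort of latent trajectories.

    Per woman: ``death_age`` (-1 = alive at max_age) and the latent
    absorbing diagnosis, if any (``dx_code`` 0=none / RES_IBC / RES_CLINICAL
    with its age and grade).  Episodes live in a flat table
    (``ep_woman, ep_onset_age, ep_grade, ep_res_code, ep_res_age``) ordered
    by onset age within each woman.
    """

    cohort_size: int
    death_age: np.ndarray
    ep_woman: np.ndarray
    ep_onset_age: np.ndarray
    ep_grade: np.ndarray
    ep_res_code: np.ndarray
    ep_res_age: np.ndarray
    dx_code: np.ndarray = field(init=False)
    dx_age: np.ndarray = field(init=False)
    dx_grade: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        n = self.cohort_size
        self.dx_code = np.zeros(n, dtype=np.int8)
        self.dx_age = np.full(n, -1, dtype=np.int16)
        self.dx_grade = np.zeros(n, dtype=np.int8)
        final = np.isin(self.ep_res_code, (RES_IBC, RES_CLINICAL))
        w = self.ep_woman[final]
        self.dx_code[w] = self.ep_res_code[final]
        self.dx_age[w] = self.ep_res_age[final]
        self.dx_grade[w] = self.ep_grade[final]

    def to_frame(self) -> pd.DataFrame:
        """Episode-level debug dump (one row per episode)."""
        return pd.DataFrame(
            {
                "woman_id": self.ep_woman,
                "death_age": self.death_age[self.ep_woman],
                "onset_age": self.ep_onset_age,
                "grade": self.ep_grade,
                "resolution": [RESOLUTION_NAMES[c] for c in self.ep_res_code],
                "resolution_age": self.ep_res_age,
            }
        )


def _simulate_block(params: ModelParameters, U: np.ndarray, validate: bool = True) -> CohortArrays:
    """Run the annual-cycle chain for a block of women.

    ``U[k, a, s]`` is woman k's uniform for cycle (age) ``a``, event slot
    ``s`` (0 death, 1 onset/progression, 2 clinical detection,
    3 regression).  Deviates are consumed positionally, never
    sequentially, so a woman's trajectory is a pure function of her own
    deviate matrix.
    """
    if validate:
        require_valid(params)
    n, n_cycles, _ = U.shape
    A = params.max_age
    assert n_cycles == A + 1

    death_p = params.death.slice(0, A)
    onset = np.stack([params.onset[g].slice(0, A) for g in GRADES], axis=1)
    onset_cum = np.cumsum(onset, axis=1)  # (A+1, 3) thresholds
    prog = params.progression_base.slice(0, A)
    prog_by_grade = np.stack(
        [prog * params.progression_multiplier[g] for g in GRADES], axis=1
    )
    clin = params.clinical_detection
    reg = params.regression
    regressed_state = _HEALTHY if params.allow_reonset else _HEALTHY_NO_REONSET

    state = np.zeros(n, dtype=np.int8)
    death_age = np.full(n, -1, dtype=np.int16)
    cur_ep = np.full(n, -1, dtype=np.int64)
    n_ep = 0
    ep_woman_parts: list[np.ndarray] = []
    ep_onset_parts: list[np.ndarray] = []
    ep_grade_parts: list[np.ndarray] = []
    res_idx_parts: list[np.ndarray] = []
    res_code_parts: list[np.ndarray] = []
    res_age_parts: list[np.ndarray] = []

    def _resolve(mask: np.ndarray, code: int, age: int) -> None:
        nonlocal cur_ep
        idx = cur_ep[mask]
        res_idx_parts.append(idx)
        res_code_parts.append(np.full(idx.size, code, dtype=np.int8))
        res_age_parts.append(np.full(idx.size, age, dtype=np.int16))
        cur_ep[mask] = -1

    for a in range(A + 1):
        healthy = state == _HEALTHY
        inert = state == _HEALTHY_NO_REONSET
        in_dcis = (state >= 1) & (state <= 3)  # snapshot: onset this cycle excluded

        # --- healthy-state cycle: death, then onset -----------------------
        u0 = U[:, a, 0]
        died_h = (healthy | inert) & (u0 < death_p[a])
        state[died_h] = _DEAD
        death_age[died_h] = a
        cand = healthy & ~died_h
        if cand.any() and onset_cum[a, 2] > 0.0:
            u1 = U[:, a, 1]
            new = cand & (u1 < onset_cum[a, 2])
            if new.any():
                grade = (
                    1 + (u1[new] >= onset_cum[a, 0]) + (u1[new] >= onset_cum[a, 1])
                ).astype(np.int8)
                w = np.flatnonzero(new)
                ep_woman_parts.append(w)
                ep_onset_parts.append(np.full(w.size, a, dtype=np.int16))
                ep_grade_parts.append(grade)
                cur_ep[w] = n_ep + np.arange(w.size)
                n_ep += w.size
                state[w] = grade

        # --- DCIS-state cycle: death, progression, clinical, regression ---
        if in_dcis.any():
            died_d = in_dcis & (u0 < death_p[a])
            state[died_d] = _DEAD
            death_age[died_d] = a
            rem = in_dcis & ~died_d
            if rem.any():
                pg = np.zeros(n)
                pg[rem] = prog_by_grade[a, state[rem] - 1]
                progressed = rem & (U[:, a, 1] < pg)
                if progressed.any():
                    _resolve(progressed, RES_IBC, a)
                    state[progressed] = _DIAGNOSED
                rem &= ~progressed
                detected = rem & (U[:, a, 2] < clin)
                if detected.any():
                    _resolve(detected, RES_CLINICAL, a)
                    state[detected] = _DIAGNOSED
                rem &= ~detected
                regressed = rem & (U[:, a, 3] < reg)
                if regressed.any():
                    _resolve(regressed, RES_REGRESSED, a)
                    state[regressed] = regressed_state

    ep_woman = np.concatenate(ep_woman_parts) if ep_woman_parts else np.empty(0, np.int64)
    ep_onset = np.concatenate(ep_onset_parts) if ep_onset_parts else np.empty(0, np.int16)
    ep_grade = np.concatenate(ep_grade_parts) if ep_grade_parts else np.empty(0, np.int8)
    ep_res_code = np.zeros(n_ep, dtype=np.int8)
    ep_res_age = np.full(n_ep, -1, dtype=np.int16)
    if res_idx_parts:
        idx = np.concatenate(res_idx_parts)
        ep_res_code[idx] = np.concatenate(res_code_parts)
        ep_res_age[idx] = np.concatenate(res_age_parts)

    # order the episode table by (woman, onset age) for predictable output
    order = np.lexsort((ep_onset, ep_woman))
    return CohortArrays(
        cohort_size=n,
        death_age=death_age,
        ep_woman=ep_woman[order],
        ep_onset_age=ep_onset[order],
        ep_grade=ep_grade[order],
        ep_res_code=ep_res_code[order],
        ep_res_age=ep_res_age[order],
    )


def simulate_cohort_arrays(
    params: ModelParameters,
    cohort_size: int,
    cohort_seed: int,
    chunk_size: int = 50_000,
) -> CohortArrays:
    """Simulate a cohort in chunks; trajectory i depends only on (seed, i)."""
    require_valid(params)
    A = params.max_age
    parts: list[CohortArrays] = []
    for lo in range(0, cohort_size, chunk_size):
        ids = np.arange(lo, min(lo + chunk_size, cohort_size))
        U = uniform_block(cohort_seed, ids, "natural_history", (A + 1, N_CYCLE_SLOTS))
        block = _simulate_block(params, U, validate=False)
        block.ep_woman = block.ep_woman + lo
        parts.append(block)
    if len(parts) == 1:
        block = parts[0]
        block.cohort_size = cohort_size
        return CohortArrays(
            cohort_size=cohort_size,
            death_age=block.death_age,
            ep_woman=block.ep_woman,
            ep_onset_age=block.ep_onset_age,
            ep_grade=block.ep_grade,
            ep_res_code=block.ep_res_code,
            ep_res_age=block.ep_res_age,
        )
    return CohortArrays(
        cohort_size=cohort_size,
        death_age=np.concatenate([p.death_age for p in parts]),
        ep_woman=np.concatenate([p.ep_woman for p in parts]),
        ep_onset_age=np.concatenate([p.ep_onset_age for p in parts]),
        ep_grade=np.concatenate([p.ep_grade for p in parts]),
        ep_res_code=np.concatenate([p.ep_res_code for p in parts]),
        ep_res_age=np.concatenate([p.ep_res_age for p in parts]),
    )


def trajectories_from_arrays(cohort: CohortArrays) -> list[LatentTrajectory]:
    episodes: list[list[DcisEpisode]] = [[] for _ in range(cohort.cohort_size)]
    for w, onset, grade, code, r_age in zip(
        cohort.ep_woman, cohort.ep_onset_age, cohort.ep_grade, cohort.ep_res_code, cohort.ep_res_age
    ):
        episodes[w].append(
            DcisEpisode(
                onset_age=int(onset),
                grade=int(grade),
                resolution=RESOLUTION_NAMES[int(code)],
                resolution_age=None if r_age < 0 else int(r_age),
            )
        )
    return [
        LatentTrajectory(
            woman_id=i,
            death_age=None if cohort.death_age[i] < 0 else int(cohort.death_age[i]),
            episodes=tuple(eps),
        )
        for i, eps in enumerate(episodes)
    ]


def simulate_trajectory(params: ModelParameters, stream: RandomStream) -> LatentTrajectory:
    """Simulate one woman's latent life course from her own stream."""
    if stream.purpose != "natural_history":
        raise ValueError(f"stream purpose must be natural_history, got {stream.purpose!r}")
    A = params.max_age
    U = stream.generator().random((A + 1, N_CYCLE_SLOTS))[None, :, :]
    block = _simulate_block(params, U)
    block.ep_woman = block.ep_woman * 0  # single woman block
    traj = trajectories_from_arrays(block)[0]
    return LatentTrajectory(
        woman_id=stream.woman_id, death_age=traj.death_age, episodes=traj.episodes
    )


def simulate_cohort(
    params: ModelParameters, cohort_size: int, cohort_seed: int
) -> list[LatentTrajectory]:
    """List-of-trajectories view of :func:`simulate_cohort_arrays`."""
    return trajectories_from_arrays(
        simulate_cohort_arrays(params, cohort_size, cohort_seed)
    )
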