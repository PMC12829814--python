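"""Exact enumeration of the coupled screened/unscreened outcome distribution.

Because screening never perturbs the latent chain, the paired design is
equivalent to the latent chain augmented with an observation flag (which
grade, if any, a screen has detected).  Propagating probability mass
through that joint chain with the simulator's exact intra-cycle event
order yields the exact probabilities of every pair classification —
overdiagnosed, diagnosed in both arms, diagnosed in the unscreened arm
only, no diagnosis — and hence the exact proportion and rate.  This is
the ground-truth oracle for the Monte-Carlo estimator on small horizons.

Intra-cycle order at age ``a`` (identical to the simulator):

1. healthy-state events: death, then onset (new DCIS is screen-eligible
   at the age-``a`` round but draws no DCIS-state events until ``a+1``);
2. the screen, if a round falls at ``a``: undetected DCIS mass moves to
   the detected flag with probability compliance x sensitivity;
3. DCIS-state events for women already in DCIS at cycle start: death,
   progression, clinical detection, regression, as sequential Bernoulli
   splits with the probabilities used as given.

Mass conservation is checked each cycle to 1e-12.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .overdiagnosis import ObservationWindow
from .parameters import GRADES, ModelParameters, ScreeningPolicy, require_valid

#: enumeration guard: horizons beyond this are refused (use Monte Carlo)
MAX_HORIZON_CYCLES = 60

MASS_TOL = 1e-12

_DEFAULT_ORDER = ("progression", "clinical", "regression")


@dataclass
class OracleResult:
    """Exact pair-classification distribution and headline statistics."""

    classes: dict[str, float]
    p_screen_detected: float
    p_diagnosed_screened: float
    p_diagnosed_unscreened: float
    expected_screens: float  # E[# screens performed per woman]
    od_by_grade: dict[int, float]
    diagnosed_by_grade: dict[int, float]
    proportion: float | None
    rate_per_100k: float | None
    window: ObservationWindow
    mass_errors: list[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"outcome": k, "probability": v} for k, v in self.classes.items()]
        rows.append({"outcome": "screen_detected", "probability": self.p_screen_detected})
        return pd.DataFrame(rows)


def exact_outcome_distribution(
    params: ModelParameters,
    policy: ScreeningPolicy,
    follow_up_years: int,
    start_age: int = 0,
    population_scale: float | None = None,
    _dcis_event_order: tuple[str, str, str] = _DEFAULT_ORDER,
) -> OracleResult:
    """Enumerate the joint chain from ``start_age`` through the window end.

    With ``start_age > 0`` the chain starts healthy and alive at
    ``start_age``; this matches the birth-start simulator exactly whenever
    death and onset are zero below ``start_age`` (as in the constant-hazard
    fixtures).  Requires per-round attendance (the all-or-none model is
    not a per-round mass split).  ``_dcis_event_order`` permutes the
    DCIS-state event sequence; it exists only so tests can pin the
    documented convention.
    """
    require_valid(params)
    if policy.attendance_model != "per_round":
        raise ValueError("oracle supports per_round attendance only")
    if sorted(_dcis_event_order) != sorted(_DEFAULT_ORDER):
        raise ValueError(f"_dcis_event_order must permute {_DEFAULT_ORDER}")

    rounds = policy.round_ages()
    A = params.max_age
    window = ObservationWindow.from_policy(policy, follow_up_years, A)
    w0, w1 = window.window_start_age, window.window_end_age
    horizon = w1 - start_age + 1
    if horizon > MAX_HORIZON_CYCLES:
        raise ValueError(
            f"horizon {horizon} cycles exceeds enumeration guard "
            f"{MAX_HORIZON_CYCLES}; raise start_age or use Monte Carlo"
        )

    death = params.death.slice(0, A)
    onset = np.array([[params.onset[g].value_at(a) for g in GRADES] for a in range(A + 1)])
    prog = np.array(
        [params.progression_base.slice(0, A) * params.progression_multiplier[g] for g in GRADES]
    ).T  # (A+1, 3)
    clin = params.clinical_detection
    reg = params.regression
    q = policy.compliance * params.sensitivity
    round_set = set(rounds)

    # live[latent, obs]: latent 0=healthy, 1..3=DCIS(grade), 4=inert healthy
    # (post-regression when re-onset is disabled); obs 0=undetected,
    # 1..3=screen-detected with that grade.
    live = np.zeros((5, 4))
    live[0, 0] = 1.0

    od = np.zeros(4)  # by screened-arm grade, index 0 unused
    both = np.zeros(4)
    p_no_dx = 0.0
    p_unscreened_only = 0.0  # structurally zero; kept for the class map
    p_screen_detected = 0.0
    expected_screens = 0.0
    mass_errors: list[float] = []
    absorbed = 0.0

    def _classify_latent_dx(mass_by_obs: np.ndarray, latent_grade: int, a: int) -> None:
        """Latent diagnosis at age a for each observation flag."""
        nonlocal p_no_dx, absorbed
        u_in = w0 <= a <= w1
        for obs in range(4):
            m = mass_by_obs[obs]
            if m == 0.0:
                continue
            if obs > 0:  # screened arm already diagnosed by the screen
                if u_in:
                    both[obs] += m
                else:
                    od[obs] += m
            else:  # screened arm inherits the latent diagnosis
                if u_in:
                    both[latent_grade] += m
                else:
                    p_no_dx += m
            absorbed += m

    def _absorb_death(mass_by_obs: np.ndarray) -> None:
        nonlocal p_no_dx, absorbed
        for obs in range(4):
            m = mass_by_obs[obs]
            if m == 0.0:
                continue
            if obs > 0:
                od[obs] += m
            else:
                p_no_dx += m
            absorbed += m

    for a in range(start_age, w1 + 1):
        new = np.zeros_like(live)
        just_onset = np.zeros((4, 4))  # [grade, obs]

        # 1. healthy-state events -----------------------------------------
        for latent in (0, 4):
            row = live[latent].copy()
            if row.sum() == 0.0:
                continue
            dead = row * death[a]
            _absorb_death(dead)
            survive = row - dead
            if latent == 0:
                for gi, g in enumerate(GRADES):
                    just_onset[g] += survive * onset[a, gi]
                survive = survive * (1.0 - onset[a].sum())
            new[latent] += survive

        dcis_mass = live[1:4].copy()  # women in DCIS at cycle start [grade-1, obs]

        # 2. the screen ----------------------------------------------------
        if a in round_set:
            # screens performed: undetected, undiagnosed women present at
            # the round (healthy survivors of this cycle, just-onset, and
            # women in DCIS at cycle start) who attend
            present = (
                new[0, 0] + new[4, 0] + just_onset[1:4, 0].sum() + dcis_mass[:, 0].sum()
            )
            expected_screens += policy.compliance * present
            if q > 0.0:
                for g in GRADES:
                    moved = just_onset[g, 0] * q
                    just_onset[g, 0] -= moved
                    just_onset[g, g] += moved
                    p_screen_detected += moved
                    moved = dcis_mass[g - 1, 0] * q
                    dcis_mass[g - 1, 0] -= moved
                    dcis_mass[g - 1, g] += moved
                    p_screen_detected += moved

        # 3. DCIS-state events for pre-existing DCIS -----------------------
        for g in GRADES:
            row = dcis_mass[g - 1]
            if row.sum() == 0.0:
                continue
            dead = row * death[a]
            _absorb_death(dead)
            remaining = row - dead
            for event in _dcis_event_order:
                p_event = {"progression": prog[a, g - 1], "clinical": clin, "regression": reg}[event]
                m = remaining * p_event
                remaining = remaining - m
                if event == "regression":
                    target = 0 if params.allow_reonset else 4
                    new[target] += m
                else:
                    _classify_latent_dx(m, g, a)
            new[g] += remaining

        for g in GRADES:
            new[g] += just_onset[g]
        live = new
        total = live.sum() + absorbed
        mass_errors.append(abs(total - 1.0))
        if mass_errors[-1] > MASS_TOL:
            raise AssertionError(
                f"mass conservation violated at age {a}: |1 - total| = {mass_errors[-1]:.3e}"
            )

    # beyond the window end nothing can change any classification
    for latent in range(5):
        _absorb_death(live[latent])  # same bookkeeping: obs>0 -> od, else none

    p_od = float(od.sum())
    p_both = float(both.sum())
    p_s = p_od + p_both
    scale = params.population_scale if population_scale is None else population_scale
    diagnosed_by_grade = {g: float(od[g] + both[g]) for g in GRADES}
    return OracleResult(
        classes={
            "overdiagnosed": p_od,
            "diagnosed_both": p_both,
            "diagnosed_unscreened_only": p_unscreened_only,
            "no_diagnosis": float(p_no_dx),
        },
        p_screen_detected=float(p_screen_detected),
        p_diagnosed_screened=p_s,
        p_diagnosed_unscreened=p_both,
        expected_screens=float(expected_screens),
        od_by_grade={g: float(od[g]) for g in GRADES},
        diagnosed_by_grade=diagnosed_by_grade,
        proportion=(p_od / p_s) if p_s > 0 else None,
        rate_per_100k=(
            1e5 * p_od / (scale * expected_screens) if expected_screens > 0 else None
        ),
        window=window,
        mass_errors=mass_errors,
    )
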