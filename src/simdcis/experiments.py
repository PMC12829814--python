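"""Determinant sweeps: follow-up, start age, interval x compliance, scale.

Each sweep is a seeded scenario grid with common random numbers across
cells: all cells of a sweep share the cohort seeds, so every cell sees the
identical latent trajectories (the unscreened arm is literally the same
across cells) and differences between cells reflect only the policy.
The follow-up sweep goes further and re-windows one set of simulated
pairs, which makes the lead-time monotonicity hold seed-by-seed, not just
in expectation.

All functions return tidy tables (per-cohort rows plus an across-cohort
summary) mirroring the study's reporting: proportion overdiagnosed and
rate per 100,000 screened women, overall and by grade.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import cohort_seed as derive_cohort_seed
from .natural_history import simulate_cohort_arrays
from .overdiagnosis import (
    GRADE_LEVELS,
    ObservationWindow,
    _denominator,
    pair_counts,
    summarize,
)
from .parameters import (
    ModelParameters,
    ParameterError,
    ScenarioConfig,
    ScreeningPolicy,
    require_valid,
)
from .screening import apply_screening_cohort, cohort_round_uniforms

FOLLOW_UPS = (2, 3, 4, 5, 10, 15, 20, 25)
START_AGES = tuple(range(40, 75, 2))
INTERVALS = (1, 2, 3, 4, 5)
COMPLIANCES = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0, 0.76)


@dataclass(frozen=True)
class SweepSpec:
    """Declarative description of one sweep (used by the CLI)."""

    sweep_kind: str  # follow_up | start_age_single_screen | interval_by_compliance | sensitivity_population_scale
    base_policy: ScreeningPolicy
    master_seed: int
    grid: tuple = ()


@dataclass
class SweepResult:
    per_cohort: pd.DataFrame
    summary: pd.DataFrame

    def cell(self, **coords) -> pd.DataFrame:
        out = self.summary
        for k, v in coords.items():
            out = out[out[k] == v]
        return out


def _run_cells(
    params: ModelParameters,
    scenario: ScenarioConfig,
    cells: list[tuple[dict, ScreeningPolicy]],
    follow_ups: tuple[int, ...],
) -> SweepResult:
    """Shared sweep engine: one simulation per cohort, reused by every cell."""
    require_valid(params)
    rows = []
    for c in range(scenario.n_cohorts):
        seed = derive_cohort_seed(scenario.master_seed, c)
        cohort = simulate_cohort_arrays(params, scenario.cohort_size, seed)
        att_u, test_u = cohort_round_uniforms(seed, scenario.cohort_size)
        for coords, policy in cells:
            arm = apply_screening_cohort(cohort, policy, params.sensitivity, att_u, test_u)
            for fu in follow_ups:
                window = ObservationWindow.from_policy(
                    policy, fu, params.max_age, scenario.outcome_age_window
                )
                counts = pair_counts(cohort, arm, window)
                for level in GRADE_LEVELS:
                    cc = counts[level]
                    denom = _denominator(scenario, cc)
                    rows.append(
                        {
                            **coords,
                            "follow_up_years": fu,
                            "grade": level,
                            "cohort": c,
                            **cc,
                            "n_screened_women": denom,
                            "proportion": (
                                cc["n_overdiagnosed"] / cc["n_diagnosed_screened"]
                                if cc["n_diagnosed_screened"] > 0
                                else np.nan
                            ),
                            "rate_per_100k": (
                                1e5 * cc["n_overdiagnosed"] / (params.population_scale * denom)
                                if denom > 0
                                else np.nan
                            ),
                        }
                    )
    per_cohort = pd.DataFrame(rows)
    keys = [k for k in per_cohort.columns if k in
            ("start_age", "interval", "compliance", "follow_up_years", "grade")]
    summary = summarize(per_cohort, by=keys)
    return SweepResult(per_cohort=per_cohort, summary=summary)


def run_follow_up_sweep(
    params: ModelParameters,
    scenario: ScenarioConfig,
    follow_ups: tuple[int, ...] = FOLLOW_UPS,
) -> SweepResult:
    """Base-policy estimate re-windowed over follow-up times.

    One row per follow-up x grade; every row derives from the same
    simulated cohorts, only the observation window changes.
    """
    return _run_cells(params, scenario, [({}, scenario.policy)], follow_ups)


def run_start_age_sweep(
    params: ModelParameters,
    scenario: ScenarioConfig,
    ages: tuple[int, ...] = START_AGES,
    follow_ups: tuple[int, ...] = FOLLOW_UPS,
) -> SweepResult:
    """One single-screen policy per start age, shared cohorts across ages."""
    cells = []
    for age in ages:
        policy = dataclasses.replace(
            scenario.policy, start_age=age, stop_age=max(age, scenario.policy.stop_age),
            single_round=True,
        )
        cells.append(({"start_age": age}, policy))
    return _run_cells(params, scenario, cells, follow_ups)


def run_interval_compliance_grid(
    params: ModelParameters,
    scenario: ScenarioConfig,
    intervals: tuple[int, ...] = INTERVALS,
    compliances: tuple[float, ...] = COMPLIANCES,
    follow_up: int = 25,
) -> SweepResult:
    """All interval x compliance combinations at one follow-up."""
    cells = []
    for interval in intervals:
        for compliance in compliances:
            policy = dataclasses.replace(
                scenario.policy, interval=interval, compliance=compliance, single_round=False
            )
            cells.append(({"interval": interval, "compliance": compliance}, policy))
    return _run_cells(params, scenario, cells, (follow_up,))


def run_population_scale_sensitivity(
    params: ModelParameters, scenario: ScenarioConfig, scale: float = 0.82
) -> pd.DataFrame:
    """Base-scenario rates under population_scale 1.0 and ``scale``.

    The scale enters only the rate denominator; the counts and therefore
    the proportion are identical by construction, so the rescaled rate is
    computed from the same per-cohort counts.
    """
    if not 0.0 < scale <= 1.0:
        raise ParameterError(f"population_scale {scale} outside (0, 1]")
    base = _run_cells(
        params, scenario.with_(), [({}, scenario.policy)], (scenario.follow_up_years,)
    )
    out = base.summary.copy()
    out = out.rename(columns={"rate_mean": "rate_scale_1", "rate_se": "rate_se_scale_1"})
    out["population_scale"] = scale
    out["rate_scaled"] = out["rate_scale_1"] / scale
    out["rate_se_scaled"] = out["rate_se_scale_1"] / scale
    return out


def summary_table(
    follow_up: SweepResult,
    start_age: SweepResult,
    grid: SweepResult,
    long_follow_up: int = 25,
    short_follow_up: int = 2,
) -> pd.DataFrame:
    """Determinant summary derived purely from the sweep outputs.

    Each row gives a determinant's direction and endpoint magnitude
    (difference between the extreme grid cells), matching the study's
    summary reporting; nothing is re-simulated.
    """

    def _pick(df: pd.DataFrame, **coords) -> pd.Series:
        sub = df[df["grade"] == "all"]
        for k, v in coords.items():
            sub = sub[sub[k] == v]
        if len(sub) != 1:
            raise ValueError(f"expected one row for {coords}, got {len(sub)}")
        return sub.iloc[0]

    rows = []

    fu_short = _pick(follow_up.summary, follow_up_years=short_follow_up)
    fu_long = _pick(follow_up.summary, follow_up_years=long_follow_up)
    rows.append(
        {
            "determinant": "follow_up_time",
            "change": f"{short_follow_up}y -> {long_follow_up}y",
            "proportion_delta": fu_long["proportion_mean"] - fu_short["proportion_mean"],
            "rate_delta": fu_long["rate_mean"] - fu_short["rate_mean"],
        }
    )

    ages = sorted(start_age.summary["start_age"].unique())
    sa_lo = _pick(start_age.summary, start_age=50, follow_up_years=long_follow_up)
    sa_hi = _pick(start_age.summary, start_age=ages[-1], follow_up_years=long_follow_up)
    rows.append(
        {
            "determinant": "screening_start_age",
            "change": f"50y -> {ages[-1]}y (single screen, {long_follow_up}y follow-up)",
            "proportion_delta": sa_hi["proportion_mean"] - sa_lo["proportion_mean"],
            "rate_delta": sa_hi["rate_mean"] - sa_lo["rate_mean"],
        }
    )

    base_comp = grid.summary["compliance"].iloc[
        (grid.summary["compliance"] - 0.76).abs().argmin()
    ]
    iv_lo = _pick(grid.summary, interval=1, compliance=base_comp)
    iv_hi = _pick(grid.summary, interval=5, compliance=base_comp)
    rows.append(
        {
            "determinant": "screening_interval",
            "change": f"1y -> 5y (compliance {base_comp:g})",
            "proportion_delta": iv_hi["proportion_mean"] - iv_lo["proportion_mean"],
            "rate_delta": iv_hi["rate_mean"] - iv_lo["rate_mean"],
        }
    )

    cp_lo = _pick(grid.summary, interval=2, compliance=0.5)
    cp_hi = _pick(grid.summary, interval=2, compliance=1.0)
    rows.append(
        {
            "determinant": "screening_compliance",
            "change": "50% -> 100% (biennial)",
            "proportion_delta": cp_hi["proportion_mean"] - cp_lo["proportion_mean"],
            "rate_delta": cp_hi["rate_mean"] - cp_lo["rate_mean"],
        }
    )

    out = pd.DataFrame(rows)
    out["proportion_direction"] = np.where(out["proportion_delta"] > 0, "increase", "decrease")
    out["rate_direction"] = np.where(out["rate_delta"] > 0, "increase", "decrease")
    return out
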