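"""Model parameters, screening policy, and scenario configuration.

The natural-history model is a discrete annual-cycle Markov chain on the
states healthy / DCIS(grade 1-3) / absorbed (death, clinical detection,
progression to invasive breast cancer).  All rates are annual transition
probabilities indexed by integer age; grade-specific progression factors
as an age-dependent base times a grade multiplier.  Screening overlays a
policy (start/stop age, interval, compliance, per-screen sensitivity) on
the latent chain.

This module owns the parameter containers, their validation, and the
file formats (YAML scalars + CSV age schedules) used by the CLI and the
analysis drivers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

GRADES = (1, 2, 3)

#: Slack for floating-point comparisons in probability-mass checks.
_MASS_TOL = 1e-9


class ParameterError(ValueError):
    """A parameter file or parameter set violates the model contract."""


# ---------------------------------------------------------------------------
# Age schedules
# ---------------------------------------------------------------------------


class AgeSchedule:
    """Annual probability indexed by integer age over a contiguous range.

    Values are per-person-year probabilities in [0, 1]; lookups outside
    ``[age_min, age_max]`` raise :class:`ParameterError`.
    """

    __slots__ = ("age_min", "age_max", "values")

    def __init__(self, age_min: int, values: Iterable[float]):
        self.age_min = int(age_min)
        self.values = np.asarray(list(values), dtype=np.float64)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ParameterError("AgeSchedule needs a non-empty 1-d value array")
        self.age_max = self.age_min + self.values.size - 1

    @classmethod
    def from_mapping(cls, mapping: Mapping[int, float]) -> "AgeSchedule":
        ages = sorted(int(a) for a in mapping)
        if ages != list(range(ages[0], ages[-1] + 1)):
            missing = sorted(set(range(ages[0], ages[-1] + 1)) - set(ages))
            raise ParameterError(f"non-contiguous ages in schedule; missing {missing}")
        return cls(ages[0], [float(mapping[a]) for a in ages])

    @classmethod
    def constant(cls, value: float, age_min: int = 0, age_max: int = 100) -> "AgeSchedule":
        return cls(age_min, np.full(age_max - age_min + 1, float(value)))

    def value_at(self, age: int) -> float:
        if not self.age_min <= age <= self.age_max:
            raise ParameterError(
                f"age {age} outside schedule domain [{self.age_min}, {self.age_max}]"
            )
        return float(self.values[age - self.age_min])

    def slice(self, age_min: int, age_max: int) -> np.ndarray:
        """Values for ages ``age_min..age_max`` inclusive (domain-checked)."""
        if age_min < self.age_min or age_max > self.age_max:
            raise ParameterError(
                f"requested ages [{age_min}, {age_max}] exceed domain "
                f"[{self.age_min}, {self.age_max}]"
            )
        i = age_min - self.age_min
        return self.values[i : i + (age_max - age_min + 1)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"age": np.arange(self.age_min, self.age_max + 1), "value": self.values}
        )

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, AgeSchedule)
            and self.age_min == other.age_min
            and np.array_equal(self.values, other.values)
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"AgeSchedule([{self.age_min}, {self.age_max}])"


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelParameters:
    """All natural-history and detection rates of the model.

    ``death`` applies equally in the healthy and DCIS states.  ``onset``
    maps grade -> annual probability of a new DCIS episode of that grade,
    conditional on being healthy.  DCIS progresses to invasive cancer at
    ``progression_base(age) * progression_multiplier[grade]`` per year, is
    clinically detected at ``clinical_detection`` per year, and regresses
    to healthy at ``regression`` per year.  A mammogram detects prevalent
    DCIS with probability ``sensitivity`` per screen.  ``population_scale``
    rescales only the per-100,000 rate denominator (used by the analysis
    that removes the share of cancers arising without a DCIS precursor).
    """

    death: AgeSchedule
    onset: Mapping[int, AgeSchedule]
    progression_base: AgeSchedule
    progression_multiplier: Mapping[int, float]
    regression: float = 0.05
    clinical_detection: float = 0.05
    sensitivity: float = 0.86
    population_scale: float = 1.0
    max_age: int = 100
    allow_reonset: bool = True

    def with_(self, **changes) -> "ModelParameters":
        return replace(self, **changes)

    def effective_progression(self, grade: int) -> np.ndarray:
        return self.progression_base.slice(0, self.max_age) * float(
            self.progression_multiplier[grade]
        )


def validate_parameters(params: ModelParameters) -> list[str]:
    """Return all invariant violations (empty list = valid).

    Checks probability bounds, schedule coverage of ``[0, max_age]``,
    per-age probability-mass budgets for the healthy-state cycle
    (death + total onset <= 1) and each DCIS-state cycle
    (death + progression_g + clinical + regression <= 1), and grade
    ordering of the effective progression multipliers.
    """
    v: list[str] = []
    A = params.max_age

    def _check_schedule(name: str, sched: AgeSchedule) -> bool:
        if sched.age_min > 0 or sched.age_max < A:
            v.append(
                f"{name}: schedule covers [{sched.age_min}, {sched.age_max}], "
                f"needs [0, {A}]"
            )
            return False
        bad = np.flatnonzero((sched.values < 0) | (sched.values > 1))
        for i in bad:
            v.append(f"{name}: value {sched.values[i]:.6g} at age {i + sched.age_min} outside [0, 1]")
        return bad.size == 0

    ok = _check_schedule("death", params.death)
    if set(params.onset) != set(GRADES):
        v.append(f"onset: grades {sorted(params.onset)} != {list(GRADES)}")
        ok = False
    else:
        for g in GRADES:
            ok &= _check_schedule(f"onset[grade {g}]", params.onset[g])
    ok &= _check_schedule("progression_base", params.progression_base)

    for name, val in (
        ("regression", params.regression),
        ("clinical_detection", params.clinical_detection),
        ("sensitivity", params.sensitivity),
    ):
        if not 0.0 <= val <= 1.0:
            v.append(f"{name}: {val} outside [0, 1]")
    if not 0.0 < params.population_scale <= 1.0:
        v.append(f"population_scale: {params.population_scale} outside (0, 1]")
    if set(params.progression_multiplier) != set(GRADES):
        v.append(
            f"progression_multiplier: grades {sorted(params.progression_multiplier)} "
            f"!= {list(GRADES)}"
        )
        ok = False
    else:
        m = [params.progression_multiplier[g] for g in GRADES]
        for g, mg in zip(GRADES, m):
            if mg < 0:
                v.append(f"progression_multiplier[grade {g}]: {mg} negative")
        if not (m[0] <= m[1] <= m[2]):
            v.append(
                "progression_multiplier: effective progression must be "
                f"non-decreasing in grade, got {m}"
            )

    if not ok:
        return v  # mass checks need well-formed schedules

    ages = np.arange(A + 1)
    death = params.death.slice(0, A)
    onset_total = sum(params.onset[g].slice(0, A) for g in GRADES)
    healthy_mass = death + onset_total
    for a in np.flatnonzero(healthy_mass > 1.0 + _MASS_TOL):
        v.append(
            f"healthy-state cycle mass {healthy_mass[a]:.6g} > 1 at age {ages[a]} "
            "(death + total onset)"
        )
    prog = params.progression_base.slice(0, A)
    for g in GRADES:
        mass = death + prog * params.progression_multiplier[g] + params.clinical_detection + params.regression
        for a in np.flatnonzero(mass > 1.0 + _MASS_TOL):
            v.append(
                f"DCIS-state cycle mass {mass[a]:.6g} > 1 at age {ages[a]}, grade {g} "
                "(death + progression + clinical detection + regression)"
            )
    return v


def require_valid(params: ModelParameters) -> ModelParameters:
    violations = validate_parameters(params)
    if violations:
        raise ParameterError("invalid parameter set:\n  " + "\n  ".join(violations))
    return params


# ---------------------------------------------------------------------------
# Screening policy and scenario
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScreeningPolicy:
    """Invitation schedule and attendance behaviour.

    ``attendance_model`` is ``per_round`` (independent Bernoulli(compliance)
    per invitation) or ``all_or_none`` (one draw decides every round).
    ``single_round`` restricts the schedule to one screen at ``start_age``
    (used by the start-age experiment).
    """

    start_age: int = 50
    stop_age: int = 74
    interval: int = 2
    compliance: float = 0.76
    attendance_model: str = "per_round"
    single_round: bool = False

    def __post_init__(self) -> None:
        if self.start_age > self.stop_age:
            raise ParameterError(
                f"start_age {self.start_age} > stop_age {self.stop_age}"
            )
        if self.interval < 1:
            raise ParameterError(f"interval {self.interval} < 1")
        if not 0.0 <= self.compliance <= 1.0:
            raise ParameterError(f"compliance {self.compliance} outside [0, 1]")
        if self.attendance_model not in ("per_round", "all_or_none"):
            raise ParameterError(
                f"attendance_model {self.attendance_model!r} not in "
                "{'per_round', 'all_or_none'}"
            )

    def round_ages(self) -> list[int]:
        if self.single_round:
            return [self.start_age]
        return list(range(self.start_age, self.stop_age + 1, self.interval))


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation scenario: cohort layout, follow-up, policy, seeds."""

    policy: ScreeningPolicy
    cohort_size: int = 100_000
    n_cohorts: int = 10
    follow_up_years: int = 25
    master_seed: int = 2026
    outcome_age_window: tuple[int, int] = (50, 100)
    #: denominator of the per-100,000 rate: "screens" = screens actually
    #: performed (default; reproduces the reported interval/compliance
    #: directions), "attendees" = women attending >= 1 round, "cohort" =
    #: every simulated woman
    rate_denominator: str = "screens"

    def __post_init__(self) -> None:
        if self.cohort_size < 1:
            raise ParameterError(f"cohort_size {self.cohort_size} < 1")
        if self.n_cohorts < 1:
            raise ParameterError(f"n_cohorts {self.n_cohorts} < 1")
        if self.follow_up_years < 0:
            raise ParameterError(f"follow_up_years {self.follow_up_years} < 0")
        if self.rate_denominator not in ("screens", "attendees", "cohort"):
            raise ParameterError(
                f"rate_denominator {self.rate_denominator!r} not in "
                "{'screens', 'attendees', 'cohort'}"
            )

    def with_(self, **changes) -> "ScenarioConfig":
        return replace(self, **changes)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def _read_config(path: Path) -> dict:
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def _schedule_from_csv(path: Path, name: str) -> AgeSchedule:
    df = pd.read_csv(path, float_precision="round_trip")
    if not {"age", "value"} <= set(df.columns):
        raise ParameterError(f"{name}: CSV {path} must have columns age,value")
    try:
        return AgeSchedule.from_mapping(dict(zip(df["age"].astype(int), df["value"])))
    except ParameterError as err:
        raise ParameterError(f"{name}: {err}") from err


def load_parameters(path: str | Path) -> ModelParameters:
    """Load and validate a parameter bundle.

    The bundle is a YAML/JSON file with the scalar rates plus relative
    paths to CSV age schedules: ``death_csv`` and ``progression_csv``
    (columns ``age,value``) and ``onset_csv`` (columns ``age,grade,value``).
    """
    path = Path(path)
    cfg = _read_config(path)
    base = path.parent
    missing = [k for k in ("death_csv", "onset_csv", "progression_csv") if k not in cfg]
    if missing:
        raise ParameterError(f"parameter file missing fields: {missing}")

    death = _schedule_from_csv(base / cfg["death_csv"], "death")
    progression = _schedule_from_csv(base / cfg["progression_csv"], "progression_base")

    onset_df = pd.read_csv(base / cfg["onset_csv"], float_precision="round_trip")
    if not {"age", "grade", "value"} <= set(onset_df.columns):
        raise ParameterError("onset CSV must have columns age,grade,value")
    onset: dict[int, AgeSchedule] = {}
    for g, sub in onset_df.groupby("grade"):
        try:
            onset[int(g)] = AgeSchedule.from_mapping(
                dict(zip(sub["age"].astype(int), sub["value"]))
            )
        except ParameterError as err:
            raise ParameterError(f"onset[grade {g}]: {err}") from err

    multipliers = {int(g): float(v) for g, v in cfg.get(
        "progression_multiplier", {1: 1.0, 2: 1.0, 3: 1.0}
    ).items()}

    params = ModelParameters(
        death=death,
        onset=onset,
        progression_base=progression,
        progression_multiplier=multipliers,
        regression=float(cfg.get("regression", 0.05)),
        clinical_detection=float(cfg.get("clinical_detection", 0.05)),
        sensitivity=float(cfg.get("sensitivity", 0.86)),
        population_scale=float(cfg.get("population_scale", 1.0)),
        max_age=int(cfg.get("max_age", 100)),
        allow_reonset=bool(cfg.get("allow_reonset", True)),
    )
    return require_valid(params)


def save_parameters(params: ModelParameters, directory: str | Path) -> Path:
    """Write a parameter bundle (YAML + CSVs); returns the YAML path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    params.death.to_frame().to_csv(directory / "death.csv", index=False, float_format="%.17g")
    params.progression_base.to_frame().to_csv(directory / "progression.csv", index=False, float_format="%.17g")
    onset_frames = []
    for g in GRADES:
        f = params.onset[g].to_frame()
        f.insert(1, "grade", g)
        onset_frames.append(f)
    pd.concat(onset_frames).to_csv(directory / "onset.csv", index=False, float_format="%.17g")
    cfg = {
        "death_csv": "death.csv",
        "onset_csv": "onset.csv",
        "progression_csv": "progression.csv",
        "progression_multiplier": {g: float(params.progression_multiplier[g]) for g in GRADES},
        "regression": params.regression,
        "clinical_detection": params.clinical_detection,
        "sensitivity": params.sensitivity,
        "population_scale": params.population_scale,
        "max_age": params.max_age,
        "allow_reonset": params.allow_reonset,
    }
    out = directory / "parameters.yaml"
    out.write_text(yaml.safe_dump(cfg, sort_keys=False))
    return out


def load_scenario(path: str | Path) -> ScenarioConfig:
    cfg = _read_config(Path(path))
    pol = cfg.pop("policy", {})
    policy = ScreeningPolicy(**pol)
    if "outcome_age_window" in cfg:
        cfg["outcome_age_window"] = tuple(cfg["outcome_age_window"])
    return ScenarioConfig(policy=policy, **cfg)


def save_scenario(scenario: ScenarioConfig, path: str | Path) -> Path:
    path = Path(path)
    pol = scenario.policy
    cfg = {
        "policy": {
            "start_age": pol.start_age,
            "stop_age": pol.stop_age,
            "interval": pol.interval,
            "compliance": pol.compliance,
            "attendance_model": pol.attendance_model,
            "single_round": pol.single_round,
        },
        "cohort_size": scenario.cohort_size,
        "n_cohorts": scenario.n_cohorts,
        "follow_up_years": scenario.follow_up_years,
        "master_seed": scenario.master_seed,
        "outcome_age_window": list(scenario.outcome_age_window),
        "rate_denominator": scenario.rate_denominator,
    }
    path.write_text(yaml.safe_dump(cfg, sort_keys=False))
    return path
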