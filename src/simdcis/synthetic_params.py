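"""Stylized parameter sets for the natural-history model.

The calibrated age schedules behind the published model (registry-based
mortality, DCIS incidence, and progression inputs) are not public, so the
experiments here run on *stylized* stand-ins that reproduce the qualitative
structure the model relies on:

* all-cause female mortality rising exponentially with adult age
  (Gompertz-like);
* DCIS onset hazard unimodal in age, peaking in the sixth/seventh decade,
  split over grades 1-3 by a fixed mix;
* DCIS-to-invasive progression mildly increasing with age, with grade
  multipliers ordered so grade 3 is the most progressive;
* the fixed scalars of the model: 86% per-screen sensitivity, 5%/year
  clinical detection, 5%/year regression.

Absolute levels are NOT calibrated to any registry; results on these sets
are qualitative (directions, orderings, lead-time behaviour), not Dutch
point estimates.

The module also provides degenerate constant-hazard sets (onset
concentrated at a single age, age-constant DCIS-state hazards) used as
exact oracle fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .parameters import (
    GRADES,
    AgeSchedule,
    ModelParameters,
    ParameterError,
    require_valid,
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Knobs of the stylized parameter generator.

    mortality_shape is ``(level, slope)`` of ``level * exp(slope * age)``.
    ``onset_peak_level`` is the *total* (all grades) annual onset
    probability at the peak age; ``onset_width`` is the Gaussian standard
    deviation of the onset curve in years.  ``progression_level`` is the
    annual base progression probability at the reference age of 70.
    Defaults give an adult mortality around 0.2% at 50 rising to ~30% at
    100, a lifetime latent-DCIS onset around 6%, and annual progression
    of roughly 1.5% (grade 1) to 6% (grade 3) in the screening ages.
    """

    seed: int = 0
    mortality_shape: tuple[float, float] = (1.2e-5, 0.10)
    onset_peak_age: float = 62.0
    onset_peak_level: float = 2.0e-3
    onset_width: float = 12.0
    grade_mix: tuple[float, float, float] = (0.20, 0.45, 0.35)
    progression_level: float = 0.03
    grade_multipliers: tuple[float, float, float] = (0.5, 1.0, 2.0)
    #: relative jitter applied to the three levels, so distinct seeds give
    #: distinct (but structurally identical) parameter sets
    jitter: float = 0.05

    def __post_init__(self) -> None:
        if abs(sum(self.grade_mix) - 1.0) > 1e-9:
            raise ParameterError(f"grade_mix {self.grade_mix} does not sum to 1")
        for name in ("onset_peak_level", "progression_level"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ParameterError(f"{name} {val} outside [0, 1]")
        if any(m < 0 for m in self.grade_mix):
            raise ParameterError(f"grade_mix {self.grade_mix} has negative entries")


def generate_parameter_set(spec: SyntheticSpec = SyntheticSpec(), max_age: int = 100) -> ModelParameters:
    """Build a validated stylized ModelParameters from a SyntheticSpec.

    Deterministic given ``spec`` (including its seed): the seed only drives
    a small multiplicative jitter on the mortality/onset/progression levels.
    """
    rng = np.random.default_rng(np.random.SeedSequence((int(spec.seed), 0xD1C5)))
    jit = 1.0 + spec.jitter * (2.0 * rng.random(3) - 1.0)
    ages = np.arange(max_age + 1, dtype=np.float64)

    level, slope = spec.mortality_shape
    death = np.clip(level * jit[0] * np.exp(slope * ages), 0.0, 1.0)
    if not np.all(np.diff(death) > 0):
        raise ParameterError(
            "stylized mortality not strictly increasing; lower mortality_shape "
            "level/slope so the curve stays below 1 up to max_age"
        )

    bell = np.exp(-0.5 * ((ages - spec.onset_peak_age) / spec.onset_width) ** 2)
    onset_total = np.clip(spec.onset_peak_level * jit[1] * bell, 0.0, 1.0)
    onset = {
        g: AgeSchedule(0, onset_total * spec.grade_mix[g - 1]) for g in GRADES
    }

    # mild linear age trend around the reference age 70 keeps progression
    # age-dependent without overwhelming the grade ordering
    prog = np.clip(spec.progression_level * jit[2] * (0.3 + ages / 100.0), 0.0, 1.0)

    params = ModelParameters(
        death=AgeSchedule(0, death),
        onset=onset,
        progression_base=AgeSchedule(0, prog),
        progression_multiplier=dict(zip(GRADES, spec.grade_multipliers)),
        max_age=max_age,
    )
    violations = [v for v in _mass_violations(params)]
    if violations:
        raise ParameterError(
            "synthetic spec produces probability-mass violations:\n  "
            + "\n  ".join(violations)
        )
    return require_valid(params)


def _mass_violations(params: ModelParameters):
    from .parameters import validate_parameters

    for v in validate_parameters(params):
        if "cycle mass" in v:
            yield v


def constant_hazard_parameters(
    onset_age: int,
    onset_prob: float,
    grade: int,
    progression: float,
    clinical: float,
    regression: float,
    death: float,
    sensitivity: float = 0.86,
    max_age: int = 100,
) -> ModelParameters:
    """Degenerate oracle fixture: onset only at one age, age-constant hazards.

    Every woman is at risk of a single-grade onset at exactly ``onset_age``
    with probability ``onset_prob``; once in the DCIS state, progression,
    clinical detection, and regression are age-constant.  Death is an
    age-constant annual probability.  These sets make the discrete chain
    exactly enumerable, which the Markov oracle exploits.
    """
    if grade not in GRADES:
        raise ParameterError(f"grade {grade} not in {GRADES}")
    zeros = np.zeros(max_age + 1)
    onset_values = zeros.copy()
    onset_values[onset_age] = onset_prob
    onset = {g: AgeSchedule(0, onset_values if g == grade else zeros) for g in GRADES}
    params = ModelParameters(
        death=AgeSchedule.constant(death, 0, max_age),
        onset=onset,
        progression_base=AgeSchedule.constant(progression, 0, max_age),
        progression_multiplier={1: 1.0, 2: 1.0, 3: 1.0},
        regression=regression,
        clinical_detection=clinical,
        sensitivity=sensitivity,
        max_age=max_age,
    )
    return require_valid(params)
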