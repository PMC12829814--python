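"""Pair classification, windows, and the scenario-level estimator."""

import numpy as np
import pytest

from simdcis import (
    ArmOutcome,
    ObservationWindow,
    ScenarioConfig,
    ScreeningPolicy,
    classify_pair,
    estimate_overdiagnosis,
)
from simdcis.natural_history import simulate_cohort_arrays
from simdcis.overdiagnosis import cohort_level_rows, pair_counts
from simdcis.screening import apply_screening_cohort, cohort_round_uniforms
from simdcis.synthetic_params import constant_hazard_parameters

SCREEN = "screen_detected_dcis"
CLINICAL = "clinically_detected_dcis"


class TestClassifyPair:
    def test_lead_time_only_is_not_overdiagnosis(self):
        pair = classify_pair(
            unscreened=ArmOutcome(CLINICAL, 63, 2),
            screened=ArmOutcome(SCREEN, 60, 2, attended_any=True),
            window=ObservationWindow(50, 85),
            death_age=None,
        )
        assert pair.diagnosed_in_screened_arm and not pair.overdiagnosed

    def test_regressed_unscreened_arm_is_overdiagnosis(self):
        pair = classify_pair(
            unscreened=ArmOutcome(),
            screened=ArmOutcome(SCREEN, 60, 1, attended_any=True),
            window=ObservationWindow(50, 85),
            death_age=None,
        )
        assert pair.overdiagnosed
        assert pair.grade_of_screened_dx == 1

    def test_window_truncation_creates_lead_time_misclassification(self):
        """The same pair flips to overdiagnosed when the window ends before
        the unscreened arm's later diagnosis (the lead-time effect)."""
        unscreened = ArmOutcome(CLINICAL, 76, 2)
        screened = ArmOutcome(SCREEN, 73, 2, attended_any=True)
        at_76 = classify_pair(unscreened, screened, ObservationWindow(50, 76), None)
        at_75 = classify_pair(unscreened, screened, ObservationWindow(50, 75), None)
        assert not at_76.overdiagnosed
        assert at_75.overdiagnosed

    def test_diagnosis_after_death_excluded(self):
        pair = classify_pair(
            unscreened=ArmOutcome(CLINICAL, 80, 2),
            screened=ArmOutcome(SCREEN, 60, 2, attended_any=True),
            window=ObservationWindow(50, 100),
            death_age=70,
        )
        # unscreened dx at 80 is after death at 70: cannot count
        assert pair.overdiagnosed

    def test_pre_window_diagnoses_excluded_symmetrically(self):
        pair = classify_pair(
            unscreened=ArmOutcome(CLINICAL, 45, 3),
            screened=ArmOutcome(CLINICAL, 45, 3),
            window=ObservationWindow(50, 100),
            death_age=None,
        )
        assert not pair.diagnosed_in_screened_arm and not pair.overdiagnosed


class TestEstimator:
    def test_null_screening_compliance_zero(self, onset50_fixture):
        scenario = ScenarioConfig(
            policy=ScreeningPolicy(50, 74, 2, compliance=0.0),
            cohort_size=5000, n_cohorts=2, follow_up_years=25, master_seed=3,
        )
        est = estimate_overdiagnosis(onset50_fixture, scenario)
        overall = est.per_cohort[est.per_cohort.grade == "all"]
        assert (overall.n_overdiagnosed == 0).all()
        assert (overall.n_screens == 0).all()
        assert (overall.n_attendees == 0).all()
        # rate undefined (no screens), proportion 0 (clinical dx happen)
        assert overall.rate_per_100k.isna().all()
        assert (overall.proportion == 0).all()

    def test_estimate_matches_oracle_on_constant_fixture(
        self, onset50_fixture, single_screen_50
    ):
        from simdcis.markov_oracle import exact_outcome_distribution

        scenario = ScenarioConfig(
            policy=single_screen_50, cohort_size=20_000, n_cohorts=5,
            follow_up_years=5, master_seed=5,
        )
        est = estimate_overdiagnosis(onset50_fixture, scenario)
        exact = exact_outcome_distribution(onset50_fixture, single_screen_50, 5, start_age=45)
        row = est.summary.set_index("grade").loc["all"]
        for col, target in (
            ("proportion_mean", exact.proportion),
            ("rate_mean", exact.rate_per_100k),
        ):
            se = row[col.replace("_mean", "_se")]
            assert abs(row[col] - target) < 3 * se, (col, row[col], target)

    def test_certain_eventual_diagnosis_limit(self):
        """With no regression and no death, every onset is eventually
        diagnosed without screening, so overdiagnosis vanishes once the
        window reaches max_age."""
        params = constant_hazard_parameters(50, 0.5, 3, 0.1, 0.2, 0.0, 0.0)
        scenario = ScenarioConfig(
            policy=ScreeningPolicy(50, 50, 2, 0.76, single_round=True),
            cohort_size=20_000, n_cohorts=1, follow_up_years=100, master_seed=7,
        )
        est = estimate_overdiagnosis(params, scenario)
        assert est.per_cohort[est.per_cohort.grade == "all"].n_overdiagnosed.sum() <= 1

    def test_undefined_proportion_reported_as_nan(self):
        params = constant_hazard_parameters(50, 0.0, 1, 0.1, 0.05, 0.05, 0.0)
        scenario = ScenarioConfig(
            policy=ScreeningPolicy(50, 74, 2, 0.76),
            cohort_size=1000, n_cohorts=2, master_seed=9,
        )
        est = estimate_overdiagnosis(params, scenario)
        assert est.per_cohort.proportion.isna().all()

    def test_population_scale_enters_rate_only(self, onset50_fixture, single_screen_50):
        scenario = ScenarioConfig(
            policy=single_screen_50, cohort_size=5000, n_cohorts=2,
            follow_up_years=5, master_seed=5,
        )
        base = estimate_overdiagnosis(onset50_fixture, scenario)
        scaled = estimate_overdiagnosis(
            onset50_fixture.with_(population_scale=0.82), scenario
        )
        assert np.allclose(
            scaled.per_cohort.rate_per_100k, base.per_cohort.rate_per_100k / 0.82,
            equal_nan=True,
        )
        assert np.allclose(
            scaled.per_cohort.proportion, base.per_cohort.proportion, equal_nan=True
        )

    def test_rate_denominator_flag(self, onset50_fixture, single_screen_50):
        for denom in ("screens", "attendees", "cohort"):
            scenario = ScenarioConfig(
                policy=single_screen_50, cohort_size=5000, n_cohorts=1,
                follow_up_years=5, master_seed=5, rate_denominator=denom,
            )
            est = estimate_overdiagnosis(onset50_fixture, scenario)
            row = est.per_cohort[est.per_cohort.grade == "all"].iloc[0]
            expected = {
                "screens": row.n_screens, "attendees": row.n_attendees, "cohort": 5000,
            }[denom]
            assert row.n_screened_women == expected


class TestInvariants:
    def test_follow_up_monotone_per_seed(self, stylized_params, small_scenario):
        rows = cohort_level_rows(
            stylized_params, small_scenario, follow_ups=(2, 5, 10, 25)
        )
        for (cohort, grade), sub in rows.groupby(["cohort", "grade"]):
            sub = sub.sort_values("follow_up_years")
            assert sub.n_overdiagnosed.is_monotonic_decreasing
            # diagnosed count can only grow with the window
            assert sub.n_diagnosed_screened.is_monotonic_increasing

    def test_crn_unscreened_counts_identical_across_policies(self, stylized_params):
        window = ObservationWindow(50, 99)
        n = 5000
        cohort = simulate_cohort_arrays(stylized_params, n, 41)
        att, test = cohort_round_uniforms(41, n)
        counts = []
        for interval in (1, 3):
            pol = ScreeningPolicy(50, 74, interval, 0.76)
            arm = apply_screening_cohort(cohort, pol, 0.86, att, test)
            counts.append(pair_counts(cohort, arm, window)["all"]["n_diagnosed_unscreened"])
        assert counts[0] == counts[1]

    def test_bounds(self, stylized_params, small_scenario):
        rows = cohort_level_rows(stylized_params, small_scenario)
        ok = rows.proportion.dropna()
        assert ((ok >= 0) & (ok <= 1)).all()
        assert (rows.rate_per_100k.dropna() >= 0).all()
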