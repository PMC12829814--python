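"""Screening overlay: schedules, attendance, detection, tie conventions."""

import numpy as np
import pytest

from simdcis import (
    RandomStream,
    ScreeningPolicy,
    apply_screening,
    build_schedule,
    draw_attendance,
    simulate_cohort,
    unscreened_outcome,
)
from simdcis._rng import N_ROUND_SLOTS, uniform_block
from simdcis.natural_history import DcisEpisode, LatentTrajectory, simulate_cohort_arrays
from simdcis.screening import apply_screening_cohort, cohort_round_uniforms
from simdcis.synthetic_params import constant_hazard_parameters


class TestSchedule:
    @pytest.mark.parametrize(
        "start,stop,interval,expected",
        [
            (50, 74, 2, list(range(50, 75, 2))),  # 13 biennial rounds
            (50, 74, 5, [50, 55, 60, 65, 70]),  # 75 exceeds stop
            (50, 74, 1, list(range(50, 75))),
        ],
    )
    def test_arithmetic_progression(self, start, stop, interval, expected):
        pol = ScreeningPolicy(start_age=start, stop_age=stop, interval=interval)
        assert [r.age for r in build_schedule(pol)] == expected

    def test_single_round_at_74(self):
        pol = ScreeningPolicy(start_age=74, stop_age=74, single_round=True)
        schedule = build_schedule(pol)
        assert [(r.round_index, r.age) for r in schedule] == [(0, 74)]


class TestAttendance:
    def test_certain_and_null_compliance(self, base_policy):
        schedule = build_schedule(base_policy)
        for compliance, expect in ((1.0, True), (0.0, False)):
            pol = ScreeningPolicy(50, 74, 2, compliance)
            rec = draw_attendance(pol, schedule, RandomStream(1, 0, "attendance"))
            assert rec.attended == (expect,) * len(schedule)

    def test_per_round_mean_attendance(self):
        # round-j deviates across 100,000 women: Bernoulli(0.76) mean
        u = uniform_block(3, np.arange(100_000), "attendance", (N_ROUND_SLOTS,))
        frac = (u[:, :13] < 0.76).mean()
        se = np.sqrt(0.76 * 0.24 / (100_000 * 13))
        assert abs(frac - 0.76) < 3 * se

    def test_all_or_none_is_constant_per_woman(self):
        pol = ScreeningPolicy(50, 74, 2, 0.5, attendance_model="all_or_none")
        schedule = build_schedule(pol)
        seen = set()
        for w in range(50):
            rec = draw_attendance(pol, schedule, RandomStream(9, w, "attendance"))
            assert len(set(rec.attended)) == 1
            seen.add(rec.attended[0])
        assert seen == {True, False}

    def test_wrong_stream_purpose(self, base_policy):
        with pytest.raises(ValueError, match="attendance"):
            draw_attendance(base_policy, build_schedule(base_policy), RandomStream(1, 0, "screen_test"))


def _traj(episodes, death_age=None, woman_id=0):
    return LatentTrajectory(woman_id=woman_id, death_age=death_age, episodes=tuple(episodes))


class TestApplyScreening:
    def test_null_sensitivity_reproduces_unscreened_arm(self, stylized_params, base_policy):
        n = 5000
        cohort = simulate_cohort_arrays(stylized_params, n, 17)
        att, test = cohort_round_uniforms(17, n)
        arm = apply_screening_cohort(cohort, base_policy, 0.0, att, test)
        assert not arm.screen_detected.any()
        assert np.array_equal(arm.dx_age, cohort.dx_age)
        assert np.array_equal(arm.dx_grade, cohort.dx_grade)

    def test_null_compliance_reproduces_unscreened_arm(self, stylized_params):
        pol = ScreeningPolicy(50, 74, 2, compliance=0.0)
        n = 5000
        cohort = simulate_cohort_arrays(stylized_params, n, 17)
        att, test = cohort_round_uniforms(17, n)
        arm = apply_screening_cohort(cohort, pol, stylized_params.sensitivity, att, test)
        assert not arm.screen_detected.any()
        assert arm.n_screens.sum() == 0
        assert np.array_equal(arm.dx_age, cohort.dx_age)

    def test_certain_test_detects_active_episode(self, single_screen_50):
        params = constant_hazard_parameters(50, 1.0, 3, 0.1, 0.05, 0.05, 0.0)
        n = 2000
        cohort = simulate_cohort_arrays(params, n, 19)
        att, test = cohort_round_uniforms(19, n)
        arm = apply_screening_cohort(cohort, single_screen_50, 1.0, att, test)
        assert arm.screen_detected.all()
        assert np.all(arm.dx_age == 50)
        assert np.all(arm.dx_grade == 3)

    def test_sensitivity_fraction_detected(self, onset50_fixture, single_screen_50):
        # every woman has active DCIS at the single age-50 screen
        n = 50_000
        cohort = simulate_cohort_arrays(onset50_fixture, n, 23)
        att, test = cohort_round_uniforms(23, n)
        arm = apply_screening_cohort(cohort, single_screen_50, 0.86, att, test)
        frac = arm.screen_detected.mean()
        se = np.sqrt(0.86 * 0.14 / n)
        assert abs(frac - 0.86) < 3 * se

    def test_same_age_resolution_is_still_visible(self):
        """A screen at age a observes an episode resolving at a: the screen
        precedes that cycle's natural-history events, so it wins the tie."""
        traj = _traj([DcisEpisode(48, 2, "clinically_detected", 52)])
        pol = ScreeningPolicy(52, 52, 2, 1.0, single_round=True)
        schedule = [r for r in build_schedule(pol)]
        from simdcis.screening import AttendanceRecord

        out = apply_screening(
            traj, schedule, AttendanceRecord(0, (True,)), 1.0, RandomStream(1, 0, "screen_test")
        )
        assert out.diagnosis == "screen_detected_dcis"
        assert out.diagnosis_age == 52

    def test_resolution_before_screen_is_invisible(self):
        traj = _traj([DcisEpisode(48, 2, "regressed", 51)])
        pol = ScreeningPolicy(52, 52, 2, 1.0, single_round=True)
        from simdcis.screening import AttendanceRecord

        out = apply_screening(
            traj, build_schedule(pol), AttendanceRecord(0, (True,)), 1.0,
            RandomStream(1, 0, "screen_test"),
        )
        assert out.diagnosis == "none"

    def test_per_woman_matches_vectorised(self, stylized_params, base_policy):
        n = 300
        cohort_seed = 29
        cohort = simulate_cohort_arrays(stylized_params, n, cohort_seed)
        att, test = cohort_round_uniforms(cohort_seed, n)
        arm = apply_screening_cohort(cohort, base_policy, stylized_params.sensitivity, att, test)
        schedule = build_schedule(base_policy)
        trajs = simulate_cohort(stylized_params, n, cohort_seed)
        for i in range(n):
            rec = draw_attendance(base_policy, schedule, RandomStream(cohort_seed, i, "attendance"))
            out = apply_screening(
                trajs[i], schedule, rec, stylized_params.sensitivity,
                RandomStream(cohort_seed, i, "screen_test"),
            )
            if arm.screen_detected[i]:
                assert out.diagnosis == "screen_detected_dcis"
                assert out.diagnosis_age == arm.dx_age[i]
                assert out.grade == arm.dx_grade[i]
            elif arm.dx_age[i] >= 0:
                assert out.diagnosis in ("clinically_detected_dcis", "dcis_progressed_to_ibc")
                assert out.diagnosis_age == arm.dx_age[i]
            else:
                assert out.diagnosis == "none"

    def test_screening_only_adds_or_advances(self, stylized_params, base_policy):
        n = 20_000
        cohort = simulate_cohort_arrays(stylized_params, n, 31)
        att, test = cohort_round_uniforms(31, n)
        arm = apply_screening_cohort(cohort, base_policy, stylized_params.sensitivity, att, test)
        both = (arm.dx_age >= 0) & (cohort.dx_age >= 0)
        assert np.all(arm.dx_age[both] <= cohort.dx_age[both])
        assert np.all(arm.dx_age[cohort.dx_age >= 0] >= 0)


class TestUnscreenedOutcome:
    def test_regressed_episode_is_no_diagnosis(self):
        assert unscreened_outcome(_traj([DcisEpisode(55, 1, "regressed", 60)])).diagnosis == "none"

    def test_clinical_detection(self):
        out = unscreened_outcome(_traj([DcisEpisode(60, 2, "clinically_detected", 63)]))
        assert (out.diagnosis, out.diagnosis_age, out.grade) == (
            "clinically_detected_dcis", 63, 2,
        )

    def test_progression(self):
        out = unscreened_outcome(_traj([DcisEpisode(55, 3, "progressed_to_ibc", 58)]))
        assert (out.diagnosis, out.diagnosis_age, out.grade) == (
            "dcis_progressed_to_ibc", 58, 3,
        )
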