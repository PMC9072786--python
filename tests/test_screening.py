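"""Screening tests, strategies, referral pathways and their invariants."""

import numpy as np
import pytest

from crcsim.engine import Individual, run_cohort
from crcsim.params import HealthState
from crcsim.params import TestProfile as TProfile
from crcsim.screening import (
    COLONOSCOPY,
    FIT,
    SIGMOIDOSCOPY,
    Strategy,
    apply_screening_round,
    build_standard_scenario,
    due_events,
)
from crcsim.screening import test_outcome as draw_test_result

from conftest import ScriptedRNG, make_uniform_bundle


class TestTestOutcome:
    def test_perfect_specificity_never_false_positive(self):
        profile = TProfile("X", 0.5, 0.5, 0.5, 1.0)
        rng = np.random.default_rng(0)
        assert all(
            draw_test_result(HealthState.NO_LESION, profile, rng) == "negative"
            for _ in range(200)
        )

    @pytest.mark.parametrize(
        "state,test_name,expected",
        [
            (HealthState.PRECLINICAL_CRC, FIT, 0.76),
            (HealthState.AA, SIGMOIDOSCOPY, 0.59),
            (HealthState.NAA, FIT, 0.05),
        ],
    )
    def test_positive_frequency_matches_sensitivity(
        self, default_bundle, state, test_name, expected
    ):
        profile = default_bundle.tests[test_name]
        rng = np.random.default_rng(11)
        n = 100_000
        pos = sum(draw_test_result(state, profile, rng) == "positive" for _ in range(n))
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(pos / n - expected) < 3 * se

    def test_rejects_diagnosed_state(self, default_bundle):
        with pytest.raises(ValueError):
            draw_test_result(
                HealthState.CRC_SYMPTOM_DETECTED,
                default_bundle.tests[FIT],
                np.random.default_rng(0),
            )


class TestApplyScreeningRound:
    def test_non_participant_untouched(self, default_bundle):
        strat = build_standard_scenario(2).with_participation(FIT=0.0)
        ind = Individual(id=0, sex="male", age=50, state=HealthState.AA)
        out = apply_screening_round(ind, (50, FIT), strat, default_bundle, ScriptedRNG([0.99]))
        assert not out.attended and out.test_result == "not_done"
        assert ind.state == HealthState.AA

    def test_forced_fit_pathway_removes_lesion(self, default_bundle):
        """FIT positive, colonoscopy completed, lesion detected: AA is
        removed and the outcome records the full pathway."""
        strat = build_standard_scenario(2)
        ind = Individual(id=0, sex="male", age=50, state=HealthState.AA)
        # draws: participation, FIT result, completion, colonoscopy detection
        out = apply_screening_round(
            ind, (50, FIT), strat, default_bundle, ScriptedRNG([0.0, 0.0, 0.0, 0.0])
        )
        assert out.attended and out.test_result == "positive"
        assert out.diagnostic_colonoscopy_done and out.lesion_removed
        assert ind.state == HealthState.NO_LESION

    def test_missed_referral_leaves_state(self, default_bundle):
        strat = build_standard_scenario(2)
        ind = Individual(id=0, sex="male", age=50, state=HealthState.AA)
        # participation yes, FIT positive, completion draw fails (u > 0.76)
        out = apply_screening_round(
            ind, (50, FIT), strat, default_bundle, ScriptedRNG([0.0, 0.0, 0.9])
        )
        assert out.test_result == "positive" and not out.diagnostic_colonoscopy_done
        assert ind.state == HealthState.AA

    def test_fs_naa_removed_without_referral(self, default_bundle):
        strat = Strategy(name="fs", participation={SIGMOIDOSCOPY: 1.0})
        ind = Individual(id=0, sex="female", age=58, state=HealthState.NAA)
        out = apply_screening_round(
            ind, (58, SIGMOIDOSCOPY), strat, default_bundle, ScriptedRNG([0.0, 0.0])
        )
        assert out.lesion_removed and not out.diagnostic_colonoscopy_done
        assert ind.state == HealthState.NO_LESION

    def test_fs_preclinical_composed_detection_rate(self, default_bundle):
        """Preclinical cancer with a forced-positive sigmoidoscopy becomes
        screen-detected at rate (referral completion 0.96) x (colonoscopy
        cancer sensitivity)."""
        tests = dict(default_bundle.tests)
        tests[SIGMOIDOSCOPY] = TProfile(SIGMOIDOSCOPY, 0.59, 0.59, 1.0, 0.92)
        b = make_uniform_bundle(tests=tests)
        strat = Strategy(name="fs", participation={SIGMOIDOSCOPY: 1.0})
        rng = np.random.default_rng(3)
        n = 100_000
        hits = 0
        for _ in range(n):
            ind = Individual(id=0, sex="male", age=60, state=HealthState.PRECLINICAL_CRC)
            out = apply_screening_round(ind, (60, SIGMOIDOSCOPY), strat, b, rng)
            hits += out.crc_detected
        expected = 0.96 * b.tests[COLONOSCOPY].sensitivity_crc
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(hits / n - expected) < 3 * se

    def test_screen_detection_resets_diagnosis_clock(self, default_bundle):
        strat = Strategy(name="colo", participation={COLONOSCOPY: 1.0})
        ind = Individual(id=0, sex="male", age=60, state=HealthState.PRECLINICAL_CRC)
        apply_screening_round(
            ind, (60, COLONOSCOPY), strat, default_bundle, ScriptedRNG([0.0, 0.0, 0.0])
        )
        assert ind.state == HealthState.CRC_SCREEN_DETECTED
        assert ind.years_since_dx == 0


class TestDueEvents:
    def test_annual_fit_due(self):
        strat = build_standard_scenario(2)
        ind = Individual(id=0, sex="male", age=57)
        assert due_events(strat, ind) == [(57, FIT)]

    def test_colonoscopy_gap_year_empty(self):
        strat = build_standard_scenario(8)
        ind = Individual(id=0, sex="male", age=55)
        assert due_events(strat, ind) == []

    def test_negative_colonoscopy_suppresses_rescreen(self):
        strat = Strategy(
            name="colo",
            events=((50, COLONOSCOPY), (55, COLONOSCOPY), (60, COLONOSCOPY)),
        )
        ind = Individual(id=0, sex="male", age=55, next_colonoscopy_due_age=60)
        assert due_events(strat, ind) == []
        ind.age = 60
        assert due_events(strat, ind) == [(60, COLONOSCOPY)]


class TestStandardScenarios:
    def test_schedules_match_printed_definitions(self):
        assert build_standard_scenario(1).events == ()
        assert [a for a, _ in build_standard_scenario(2).events] == list(range(50, 70))
        assert [a for a, _ in build_standard_scenario(3).events] == list(range(50, 70, 2))
        assert [a for a, _ in build_standard_scenario(5).events] == [50, 52, 54]
        s6 = build_standard_scenario(6)
        assert [e for e in s6.events if e[1] == COLONOSCOPY] == [
            (55, COLONOSCOPY),
            (65, COLONOSCOPY),
        ]
        assert build_standard_scenario(8).events == ((50, COLONOSCOPY), (60, COLONOSCOPY))

    def test_default_behaviour_parameters(self):
        s = build_standard_scenario(2)
        assert s.participation_for(FIT) == 0.94
        assert s.participation_for(COLONOSCOPY) == 0.425
        assert s.colonoscopy_completion == 0.76
        assert s.fs_colonoscopy_completion == 0.96
        assert s.rescreen_interval_after_negative_colonoscopy == 10

    def test_unknown_id_rejected(self):
        with pytest.raises(ValueError):
            build_standard_scenario(9)


class TestCohortLevelInvariants:
    def test_zero_participation_equals_no_screening(self, default_bundle):
        """With participation 0, every scenario reproduces the
        no-screening cohort bit for bit (common random numbers)."""
        ref = run_cohort(5000, default_bundle, strategy=None, seed=13)
        for sid in (2, 6, 8):
            strat = build_standard_scenario(sid).with_participation(
                **{FIT: 0.0, COLONOSCOPY: 0.0}
            )
            r = run_cohort(5000, default_bundle, strategy=strat, seed=13)
            np.testing.assert_array_equal(r.state_counts, ref.state_counts)
            np.testing.assert_array_equal(r.crc_deaths, ref.crc_deaths)
            np.testing.assert_allclose(r.py_mortality, ref.py_mortality)

    def test_perfect_annual_colonoscopy_intercepts_all_preclinical(self):
        """With a perfect test, full participation and annual colonoscopy
        from the first age, no symptom-detected cancer can ever arise
        after screening begins (every preclinical case is intercepted
        first).  The post-negative rescreen holiday is collapsed to one
        year so the schedule really is annual."""
        tests = {
            FIT: TProfile(FIT, 1.0, 1.0, 1.0, 1.0),
            COLONOSCOPY: TProfile(COLONOSCOPY, 1.0, 1.0, 1.0, 1.0),
            SIGMOIDOSCOPY: TProfile(SIGMOIDOSCOPY, 1.0, 1.0, 1.0, 1.0),
        }
        b = make_uniform_bundle(tests=tests)
        strat = Strategy(
            name="annual_colo",
            events=tuple((a, COLONOSCOPY) for a in range(40, 80)),
            participation={COLONOSCOPY: 1.0},
            colonoscopy_completion=1.0,
            rescreen_interval_after_negative_colonoscopy=1,
        )
        r = run_cohort(20_000, b, strategy=strat, seed=29)
        assert r.inc_symptom.sum() == 0
        assert r.inc_screen.sum() > 0  # initial preclinical pool is found

    def test_screening_never_worsens_severity(self, default_bundle):
        """Screening only removes lesions or relabels preclinical cancer
        as screen-detected: the undiagnosed pool under screening is never
        more severe than without screening (common random numbers)."""
        ref = run_cohort(20_000, default_bundle, strategy=None, seed=37)
        scr = run_cohort(
            20_000, default_bundle, strategy=build_standard_scenario(2), seed=37
        )
        # fewer or equal advanced adenomas + preclinical cancers at 70
        idx = 70 - 40
        ref_adv = ref.state_counts[idx, :, 2:4].sum()
        scr_adv = scr.state_counts[idx, :, 2:4].sum()
        assert scr_adv <= ref_adv
        # and total diagnosed + dead from cancer never exceeds reference
        assert (
            scr.inc_screen.sum() + scr.inc_symptom.sum()
            <= ref.inc_screen.sum() + ref.inc_symptom.sum()
        )
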