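"""Strain profiles, effective release sizes and release schedules."""

import numpy as np
import pytest

import medflysit as m
from medflysit.mating import MatingState
from tests.conftest import adult_population

CFG = m.SimConfig()


class TestEffectiveReleaseMultiplier:
    def test_standard_sit_baseline(self):
        assert m.effective_release_multiplier(1.0, 0.0) == 1.0

    def test_sex_conversion_line_is_15_percent_higher(self):
        mult = m.effective_release_multiplier(0.85, 0.35)
        assert mult == pytest.approx(1.1475, abs=1e-12)
        assert round((mult - 1.0) * 100) == 15

    def test_low_conversion_line_is_1_percent_higher(self):
        assert m.effective_release_multiplier(1.0, 0.011) == pytest.approx(1.011)

    @pytest.mark.parametrize("surv,xx", [(-0.1, 0.0), (1.2, 0.0), (1.0, -0.2),
                                         (1.0, 1.5)])
    def test_out_of_range_rejected(self, surv, xx):
        with pytest.raises(m.InvalidParameterError):
            m.effective_release_multiplier(surv, xx)


class TestBuiltinProfiles:
    def test_five_systems_defined(self):
        assert set(m.BUILTIN_PROFILES) == {
            "standard_SIT", "DmPub2_radiation", "DmPub2_pgSIT",
            "CcPub1_radiation", "CcPub1_pgSIT",
        }

    def test_fitness_by_sterilisation_mode(self):
        for p in m.BUILTIN_PROFILES.values():
            expected = 0.83 if p.sterilisation == "radiation" else 1.0
            assert p.male_mating_fitness == expected

    def test_multiplier_ordering(self):
        mult = {n: p.release_multiplier for n, p in m.BUILTIN_PROFILES.items()}
        assert mult["CcPub1_pgSIT"] == mult["CcPub1_radiation"] == pytest.approx(1.1475)
        assert mult["DmPub2_pgSIT"] == pytest.approx(1.011)
        assert mult["CcPub1_pgSIT"] > mult["DmPub2_pgSIT"] > mult["standard_SIT"] == 1.0

    def test_unknown_profile_rejected(self):
        with pytest.raises(m.InvalidParameterError):
            m.get_profile("CcPub9")

    def test_profile_defaults_fill_in(self):
        p = m.strain_profile("custom", "radiation")
        assert p.male_mating_fitness == 0.83 and p.release_multiplier == 1.0


class TestWeeklyReleaseCount:
    STD = m.BUILTIN_PROFILES["standard_SIT"]
    CC = m.BUILTIN_PROFILES["CcPub1_pgSIT"]

    def test_zero_ratio_releases_nothing(self):
        sched = m.ReleaseSchedule(0.0)
        assert all(
            m.weekly_release_count(sched, w, 10_000, self.STD) == 0
            for w in range(1, 20)
        )

    def test_ratio_one_weekly_equals_equilibrium_males(self):
        sched = m.ReleaseSchedule(1.0)
        assert m.weekly_release_count(sched, 1, 10_000, self.STD) == 10_000

    def test_interval_release_is_scaled_and_sparse(self):
        sched = m.ReleaseSchedule(1.0, interval_weeks=4)
        counts = [m.weekly_release_count(sched, w, 10_000, self.CC)
                  for w in range(1, 9)]
        assert counts == [45_900, 0, 0, 0, 45_900, 0, 0, 0]

    @pytest.mark.parametrize("interval", [1, 2, 4, 6, 10, 13])
    def test_total_effort_is_interval_invariant(self, interval):
        weekly = m.ReleaseSchedule(1.3)
        sparse = m.ReleaseSchedule(1.3, interval_weeks=interval)
        horizon = 100
        tot_weekly = sum(m.weekly_release_count(weekly, w, 7_919, self.CC)
                         for w in range(1, horizon + 1))
        tot_sparse = sum(m.weekly_release_count(sparse, w, 7_919, self.CC)
                         for w in range(1, horizon + 1))
        per_release = m.weekly_release_count(sparse, 1, 7_919, self.CC)
        assert abs(tot_sparse - tot_weekly) <= per_release


class TestReleaseCohorts:
    def test_empty_cohort(self):
        c = m.make_release_cohort(0, m.BUILTIN_PROFILES["standard_SIT"])
        assert c.count == 0

    def test_cohort_carries_profile_fitness_and_sterility(self):
        rad = m.make_release_cohort(10, m.BUILTIN_PROFILES["CcPub1_radiation"])
        pg = m.make_release_cohort(10, m.BUILTIN_PROFILES["CcPub1_pgSIT"])
        assert rad.mating_fitness == 0.83 and rad.sterile
        assert pg.mating_fitness == 1.0 and pg.sterile

    def test_negative_count_rejected(self):
        with pytest.raises(m.InvalidParameterError):
            m.make_release_cohort(-1, m.BUILTIN_PROFILES["standard_SIT"])

    def test_injection_enters_as_adult_at_emergence_age(self, rng):
        pop = m.Population.empty(CFG)
        cohort = m.make_release_cohort(1_000, m.BUILTIN_PROFILES["CcPub1_pgSIT"])
        pop.add_released(cohort.name, cohort.mating_fitness, cohort.count)
        assert pop.released["CcPub1_pgSIT"][CFG.adult_emergence_age] == 1_000
        assert pop.released_males_alive == 1_000
        assert pop.total_wild == 0

    def test_released_males_never_father_offspring(self, rng):
        """Virgin females in a population whose only males are released:
        every mating is sterile and reproduction yields zero eggs, forever."""
        cfg = CFG.replace(expected_larvae=1e6)
        pop = adult_population(cfg, n_females=20_000, state=MatingState.VIRGIN)
        pop.add_released("CcPub1_pgSIT", 1.0, 50_000)
        for _ in range(4):
            rec = m.step_week(pop, cfg, rng)
            assert rec.eggs_laid == 0 and rec.larvae_surviving == 0
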