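"""Calibration, burn-in stationarity, replayability and outcome metrics."""

import numpy as np
import pandas as pd
import pytest

import medflysit as m


class TestCalibration:
    def test_analytic_equilibrium_structure(self, desk_config):
        cal = m.analytic_equilibrium(desk_config)
        assert cal.expected_larvae > 0
        assert cal.equilibrium_females == desk_config.scaled_init_females
        assert 0 < cal.s_star < desk_config.base_larval_survival * desk_config.beta
        assert 0 < cal.f_star
        # males outlive females, so the male standing pool is larger
        assert cal.equilibrium_males > cal.equilibrium_females

    def test_equilibrium_scales_linearly(self):
        small = m.analytic_equilibrium(m.SimConfig(scale_factor=0.1))
        full = m.analytic_equilibrium(m.SimConfig(scale_factor=1.0))
        assert small.expected_larvae == pytest.approx(full.expected_larvae * 0.1)
        assert small.equilibrium_males == pytest.approx(full.equilibrium_males * 0.1)
        assert small.f_star == pytest.approx(full.f_star)      # rates unchanged
        assert small.s_star == pytest.approx(full.s_star)

    def test_infeasible_demography_raises(self):
        # almost no eggs: no survival rate can replace the population
        cfg = m.SimConfig(poisson_mean_eggs=0.1)
        with pytest.raises(m.CalibrationError):
            m.calibrate_equilibrium(cfg, refine=False)

    def test_burn_in_is_stationary_at_desk_scale(self, desk_config, desk_calibration):
        """No-release runs hold the calibrated equilibrium: mean adult
        females over burn-in weeks 31-50 within 10% of target, 5 seeds."""
        target = desk_config.scaled_init_females
        means = []
        for seed in range(5):
            traj = m.run_simulation(desk_config, seed=seed,
                                    calibration=desk_calibration)
            burn = traj.frame[traj.frame["phase"] == "burn_in"]
            means.append(burn["adult_wild_females"].tail(20).mean())
        assert abs(np.mean(means) - target) / target < 0.10

    def test_micro_scenario_equilibrium_within_30_percent(self, micro_config):
        cal = m.calibrate_equilibrium(micro_config, seed=11)
        traj = m.run_simulation(micro_config, seed=11, calibration=cal)
        burn = traj.frame[traj.frame["phase"] == "burn_in"]
        mean = burn["adult_wild_females"].tail(20).mean()
        assert abs(mean - 100) / 100 < 0.30

    def test_equilibrium_increases_with_expected_larvae(self, micro_config):
        """More rearing capacity supports a larger stationary population."""
        cal = m.calibrate_equilibrium(micro_config, seed=3, refine=False)
        means = []
        for factor in (1.0, 3.0):
            cfg = micro_config.replace(expected_larvae=cal.expected_larvae * factor)
            pop = m.initial_population(cfg, cal)
            rng = np.random.default_rng(3)
            counts = [m.step_week(pop, cfg, rng).adult_wild_females
                      for _ in range(60)]
            means.append(np.mean(counts[-20:]))
        assert means[1] > means[0]


class TestRunSimulation:
    def test_same_seed_replays_bit_identically(self, desk_config, desk_calibration):
        sched = m.ReleaseSchedule(1.0)
        prof = m.get_profile("CcPub1_pgSIT")
        a = m.run_simulation(desk_config, prof, sched, seed=7,
                             calibration=desk_calibration)
        b = m.run_simulation(desk_config, prof, sched, seed=7,
                             calibration=desk_calibration)
        pd.testing.assert_frame_equal(a.frame, b.frame)
        assert a.elimination_week == b.elimination_week

    def test_no_release_control_matches_burn_in_behaviour(
        self, desk_config, desk_calibration
    ):
        traj = m.run_simulation(desk_config, seed=2, calibration=desk_calibration)
        rel = traj.release_frame
        target = desk_config.scaled_init_females
        assert not traj.eliminated
        assert (rel["released_males"] == 0).all()
        assert abs(rel["adult_wild_females"].mean() - target) / target < 0.10

    def test_trajectory_invariants(self, desk_config, desk_calibration):
        traj = m.run_simulation(desk_config, m.get_profile("CcPub1_pgSIT"),
                                m.ReleaseSchedule(2.0), seed=4,
                                calibration=desk_calibration)
        f = traj.frame
        counts = f[["adult_wild_females", "adult_wild_males", "released_males",
                    "wild_larvae", "wild_pupae", "eggs_laid", "larvae_surviving"]]
        assert (counts >= 0).all().all()
        assert f["week"].iloc[0] == 1 - desk_config.burn_in_weeks
        if traj.eliminated:
            assert bool(f["eliminated"].iloc[-1])
            assert not f["eliminated"].iloc[:-1].any()
            assert len(f) == desk_config.burn_in_weeks + traj.elimination_week
        else:
            assert len(f) == desk_config.burn_in_weeks + desk_config.horizon_weeks

    def test_releases_appear_on_schedule(self, desk_config, desk_calibration):
        traj = m.run_simulation(desk_config, m.get_profile("standard_SIT"),
                                m.ReleaseSchedule(0.5, interval_weeks=4),
                                seed=9, calibration=desk_calibration)
        rel = traj.release_frame
        assert (rel.loc[rel["week"] == 1, "released_males"] > 0).all()
        burn = traj.frame[traj.frame["phase"] == "burn_in"]
        assert (burn["released_males"] == 0).all()


class TestOutcomeMetrics:
    def _make_traj(self, weeks_females, horizon=100, burn_in=2):
        """Hand-built trajectory: list of (release week, females)."""
        rows = [
            {"week": w - burn_in, "phase": "burn_in", "adult_wild_females": 10,
             "adult_wild_males": 10, "released_males": 0, "wild_larvae": 0,
             "wild_pupae": 0, "eggs_laid": 0, "larvae_surviving": 0,
             "eliminated": False}
            for w in range(1, burn_in + 1)
        ]
        for w, fem in weeks_females:
            rows.append({"week": w, "phase": "release",
                         "adult_wild_females": fem, "adult_wild_males": 0,
                         "released_males": 0, "wild_larvae": 0, "wild_pupae": 0,
                         "eggs_laid": 0, "larvae_surviving": 0,
                         "eliminated": False})
        frame = pd.DataFrame(rows)
        return m.Trajectory(
            frame=frame, burn_in_weeks=burn_in, horizon_weeks=horizon,
            eliminated=False, elimination_week=None, equilibrium_males=10.0,
            calibration=m.analytic_equilibrium(m.SimConfig()),
            profile_name=None, release_ratio=0.0, interval_weeks=1, seed=0,
        )

    def test_censored_run_has_no_elimination_time(self, desk_config,
                                                  desk_calibration):
        traj = m.run_simulation(desk_config, seed=1, calibration=desk_calibration)
        assert m.time_to_elimination(traj) is None

    def test_elimination_week_is_first_zero_wild_week(self, desk_config,
                                                      desk_calibration):
        traj = m.run_simulation(desk_config, m.get_profile("CcPub1_pgSIT"),
                                m.ReleaseSchedule(5.0), seed=6,
                                calibration=desk_calibration)
        week = m.time_to_elimination(traj)
        assert week is not None and 1 <= week <= desk_config.horizon_weeks
        assert traj.frame["adult_wild_females"].iloc[-1] == 0
        assert traj.frame["eliminated"].iloc[-1]

    def test_mean_females_of_constant_tail_is_the_constant(self):
        traj = self._make_traj([(w, 7) for w in range(1, 101)])
        assert m.mean_females_last20(traj) == 7.0

    def test_post_elimination_weeks_count_as_zero(self):
        # run truncated at release week 50: the last-20 window is all zeros
        traj = self._make_traj([(w, 33) for w in range(1, 51)])
        assert m.mean_females_last20(traj) == 0.0
        # truncation at week 90: half the window is populated
        traj2 = self._make_traj([(w, 10) for w in range(1, 91)])
        assert m.mean_females_last20(traj2) == 5.0
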