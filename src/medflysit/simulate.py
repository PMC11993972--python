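"""Burn-in, calibration, release phase, elimination detection.

Calibration fixes the one free density-dependence constant
(``expected_larvae``, the weekly larval count at which the competition
factor equals 1) so that the no-release population is stationary at the
configured adult female count.  The seed value comes from the stable age
distribution implied by the survival schedules, for which the equilibrium
is available in closed form; a short pilot burn-in then corrects any
residual drift, which is possible in one step because the equilibrium
population size is exactly linear in ``expected_larvae``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .config import SimConfig
from .errors import CalibrationError, InvalidParameterError
from .mating import STATE_INDEX, MatingState
from .population import Population, step_week
from .release import ReleaseSchedule, StrainProfile, make_release_cohort, weekly_release_count

_V = STATE_INDEX[MatingState.VIRGIN]
_FF = STATE_INDEX[MatingState.FIRST_FERTILE]


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def adult_survivorship(schedule, config: SimConfig) -> np.ndarray:
    """Probability of being alive at each age, per adult recruit.

    Index a holds the probability that a fly emerging at the adult
    emergence age is still alive during its age-a week, applying background
    and age-conditional survival at the end of each adult week.
    """
    ea = config.adult_emergence_age
    n = len(schedule)
    l = np.zeros(n)
    l[ea] = 1.0
    for a in range(ea, n - 1):
        l[a + 1] = l[a] * config.adult_background_survival * schedule[a]
    return l


@dataclass(frozen=True)
class Calibration:
    """Output of equilibrium calibration (all counts at the run's scale)."""

    expected_larvae: float
    equilibrium_females: float      # adult females (the calibration target)
    equilibrium_males: float        # adult wild males (analytic)
    weekly_recruits: float          # adult recruits per sex per week
    weekly_eggs: float              # eggs laid per week at equilibrium
    f_star: float                   # equilibrium competition factor
    s_star: float                   # equilibrium larval survival rate


def analytic_equilibrium(config: SimConfig) -> Calibration:
    """Closed-form stationary state of the no-release dynamics.

    At equilibrium each week's eggs E must return R = E * s(f) adult
    recruits, with the recruit rate also fixed by egg production of the
    standing females: E = (R/2) * mean_eggs * (reproductive female-weeks per
    female recruit).  That pins the equilibrium survival rate s*, hence the
    competition factor f*, and ``expected_larvae`` follows from the target
    female count.
    """
    ea = config.adult_emergence_age
    l_f = adult_survivorship(config.female_age_survival, config)
    l_m = adult_survivorship(config.male_age_survival, config)
    female_weeks = float(l_f[ea:].sum())          # adult female-weeks per recruit
    repro_weeks = float(l_f[ea + 1:].sum())       # reproductive weeks (2nd adult week on)
    male_weeks = float(l_m[ea:].sum())

    if repro_weeks <= 0:
        raise CalibrationError("survival schedules leave no reproductive weeks")
    s_star = 2.0 / (config.poisson_mean_eggs * repro_weeks)
    s_max = config.base_larval_survival * config.beta
    if s_star >= s_max:
        raise CalibrationError(
            "no positive equilibrium: required larval survival "
            f"{s_star:.4f} exceeds the low-density maximum {s_max:.4f}"
        )
    if config.beta == 1.0:
        raise CalibrationError("beta = 1 leaves no density dependence to calibrate")
    f_star = (s_max / s_star - 1.0) / (config.beta - 1.0)

    target_females = config.scaled_init_females
    recruits = target_females / female_weeks          # per sex per week
    eggs = 2.0 * recruits / s_star
    expected_larvae = eggs / f_star
    return Calibration(
        expected_larvae=expected_larvae,
        equilibrium_females=target_females,
        equilibrium_males=recruits * male_weeks,
        weekly_recruits=recruits,
        weekly_eggs=eggs,
        f_star=f_star,
        s_star=s_star,
    )


def initial_population(config: SimConfig, calibration: Calibration) -> Population:
    """Seed the population at the stable age distribution.

    Adults are placed per-age according to survivorship; juvenile slots hold
    one weekly recruit cohort per sex each.  Adult females past their first
    adult week start mated-fertile; the emergence-age cohort starts virgin
    (it mates during the first simulated week).
    """
    ea = config.adult_emergence_age
    pop = Population.empty(config)
    R = calibration.weekly_recruits
    l_f = adult_survivorship(config.female_age_survival, config)
    l_m = adult_survivorship(config.male_age_survival, config)
    for a in range(1, ea):
        pop.females[a, _V] = round(R)
        pop.males[a] = round(R)
    pop.females[ea, _V] = round(R * l_f[ea])
    for a in range(ea + 1, len(l_f)):
        pop.females[a, _FF] = round(R * l_f[a])
    for a in range(ea, len(l_m)):
        pop.males[a] = round(R * l_m[a])
    return pop


def _burn_in_mean_females(
    config: SimConfig, calibration: Calibration, seed, window: int = 20
) -> float:
    rng = np.random.default_rng(seed)
    cfg = config.replace(expected_larvae=calibration.expected_larvae)
    pop = initial_population(cfg, calibration)
    counts = []
    for _ in range(cfg.burn_in_weeks):
        rec = step_week(pop, cfg, rng)
        counts.append(rec.adult_wild_females)
    return float(np.mean(counts[-window:]))


def calibrate_equilibrium(
    config: SimConfig,
    seed: Optional[int] = None,
    refine: bool = True,
    drift_tolerance: float = 0.02,
) -> Calibration:
    """Calibrate ``expected_larvae`` for a stationary no-release population.

    Starts from the closed-form value and, when ``refine`` is set, runs a
    pilot burn-in; if the mean adult female count over the last 20 burn-in
    weeks drifts from the target by more than ``drift_tolerance``, the
    constant is rescaled by the observed ratio (the equilibrium is linear in
    ``expected_larvae``) and verified once more.  Raises
    :class:`CalibrationError` if the verified mean still misses the target
    by more than an acceptance band that widens for very small populations,
    where demographic noise dominates.
    """
    calib = analytic_equilibrium(config)
    if not refine:
        return calib
    if seed is None:
        seed = config.seed
    pilot_seed = np.random.SeedSequence([int(seed), 0x5EED]).generate_state(1)[0]

    target = calib.equilibrium_females
    mean = _burn_in_mean_females(config, calib, pilot_seed)
    if mean <= 0:
        raise CalibrationError(
            "pilot burn-in went extinct; population too small to calibrate"
        )
    drift = abs(mean - target) / target
    if drift > drift_tolerance:
        scale = target / mean
        calib = Calibration(
            expected_larvae=calib.expected_larvae * scale,
            equilibrium_females=calib.equilibrium_females,
            equilibrium_males=calib.equilibrium_males,
            weekly_recruits=calib.weekly_recruits,
            weekly_eggs=calib.weekly_eggs * scale,
            f_star=calib.f_star,
            s_star=calib.s_star,
        )
        mean = _burn_in_mean_females(config, calib, pilot_seed + 1)
        drift = abs(mean - target) / target
    # acceptance band: 10% for large populations, wider when sqrt(N) noise
    # on a 20-week mean is itself of order 10% or more
    band = max(0.10, 3.0 / math.sqrt(max(target, 1.0)))
    if drift > band:
        raise CalibrationError(
            f"calibration failed to stabilise: mean adult females {mean:.1f} "
            f"vs target {target:.1f} (drift {drift:.1%}, allowed {band:.1%})"
        )
    return calib


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

_TRAJECTORY_COLUMNS = [
    "week",
    "phase",
    "adult_wild_females",
    "adult_wild_males",
    "released_males",
    "wild_larvae",
    "wild_pupae",
    "eggs_laid",
    "larvae_surviving",
    "eliminated",
]


@dataclass
class Trajectory:
    """Weekly records of one run plus its outcome metadata.

    ``frame`` has one row per simulated week; burn-in weeks carry
    non-positive week indices (-burn_in+1 .. 0) and release-phase weeks run
    1 .. horizon.  Recording stops at elimination (zero wild individuals in
    all stages), which is absorbing.
    """

    frame: pd.DataFrame
    burn_in_weeks: int
    horizon_weeks: int
    eliminated: bool
    elimination_week: Optional[int]     # release-phase week, None if censored
    equilibrium_males: float            # measured, used for release sizing
    calibration: Calibration
    profile_name: Optional[str]
    release_ratio: float
    interval_weeks: int
    seed: int

    @property
    def release_frame(self) -> pd.DataFrame:
        return self.frame[self.frame["phase"] == "release"]


def run_simulation(
    config: SimConfig,
    profile: Optional[StrainProfile] = None,
    schedule: Optional[ReleaseSchedule] = None,
    seed: Optional[int] = None,
    calibration: Optional[Calibration] = None,
) -> Trajectory:
    """Burn-in, then a release phase until the horizon or elimination.

    A single seeded generator drives the whole run (burn-in included), so
    the same seed and configuration replay bit-identically.  The wild male
    count that release sizes refer to is measured as the mean adult wild
    male count over the last 10 burn-in weeks.
    """
    if seed is None:
        seed = config.seed
    if calibration is None:
        calibration = calibrate_equilibrium(config, seed=seed)
    cfg = config.replace(expected_larvae=calibration.expected_larvae)
    do_releases = profile is not None and schedule is not None and (
        schedule.release_ratio > 0
    )

    rng = np.random.default_rng(int(seed))
    pop = initial_population(cfg, calibration)
    rows: list[tuple] = []
    eliminated = False
    elimination_week: Optional[int] = None

    male_window: list[int] = []
    for i in range(cfg.burn_in_weeks):
        week = i - cfg.burn_in_weeks + 1          # ... -1, 0
        rec = step_week(pop, cfg, rng)
        male_window.append(rec.adult_wild_males)
        gone = pop.total_wild == 0
        rows.append((week, "burn_in", rec.adult_wild_females, rec.adult_wild_males,
                     rec.released_males, rec.wild_larvae, rec.wild_pupae,
                     rec.eggs_laid, rec.larvae_surviving, gone))
        if gone:
            eliminated = True
            elimination_week = week
            break

    equilibrium_males = float(np.mean(male_window[-10:])) if male_window else 0.0

    if not eliminated:
        for week in range(1, cfg.horizon_weeks + 1):
            cohorts = []
            if do_releases:
                n = weekly_release_count(schedule, week, equilibrium_males, profile)
                if n > 0:
                    cohorts.append(make_release_cohort(n, profile))
            rec = step_week(pop, cfg, rng, cohorts)
            gone = pop.total_wild == 0
            rows.append((week, "release", rec.adult_wild_females,
                         rec.adult_wild_males, rec.released_males,
                         rec.wild_larvae, rec.wild_pupae, rec.eggs_laid,
                         rec.larvae_surviving, gone))
            if gone:
                eliminated = True
                elimination_week = week
                break

    frame = pd.DataFrame(rows, columns=_TRAJECTORY_COLUMNS)
    return Trajectory(
        frame=frame,
        burn_in_weeks=cfg.burn_in_weeks,
        horizon_weeks=cfg.horizon_weeks,
        eliminated=eliminated,
        elimination_week=elimination_week,
        equilibrium_males=equilibrium_males,
        calibration=calibration,
        profile_name=profile.name if profile is not None else None,
        release_ratio=schedule.release_ratio if schedule is not None else 0.0,
        interval_weeks=schedule.interval_weeks if schedule is not None else 1,
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# outcome metrics
# ---------------------------------------------------------------------------

def time_to_elimination(trajectory: Trajectory) -> Optional[int]:
    """Release-phase week of elimination, or ``None`` if censored at the
    horizon (or if the run never entered the release phase)."""
    if trajectory.elimination_week is None:
        return None
    if trajectory.elimination_week < 1:
        return 0            # already gone during burn-in: eliminated at release start
    return trajectory.elimination_week


def mean_females_last20(trajectory: Trajectory, window: int = 20) -> float:
    """Mean adult wild female count over the last ``window`` release-phase
    weeks of the horizon; weeks after elimination count as zero."""
    if trajectory.horizon_weeks < window:
        raise InvalidParameterError(
            f"horizon shorter than the {window}-week averaging window"
        )
    first = trajectory.horizon_weeks - window + 1
    rel = trajectory.release_frame
    counts = rel.set_index("week")["adult_wild_females"]
    total = 0.0
    for week in range(first, trajectory.horizon_weeks + 1):
        total += float(counts.get(week, 0.0))   # truncated (post-elimination) = 0
    return total / window
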