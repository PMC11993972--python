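"""Weekly life cycle of the wild population and released sterile males.

The population is held as exchangeable equivalence classes: integer counts
per (age, sex, mating state, origin).  Every stochastic operation draws the
class-level equivalent of per-individual sampling (binomial thinning,
fitness-weighted multinomial mate assignment, Poisson clutch totals), so the
distribution of any census statistic is identical to an explicit
per-individual simulation while remaining O(number of age classes) per week.

Weekly event order: (1) release injection, (2) mating, (3) reproduction,
(4) density-dependent larval competition on that week's clutches,
(5) mortality, aging and stage transitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np

from .config import SimConfig
from .errors import InvalidParameterError
from .mating import STATE_INDEX, MatingState

_V = STATE_INDEX[MatingState.VIRGIN]
_FF = STATE_INDEX[MatingState.FIRST_FERTILE]
_FS = STATE_INDEX[MatingState.FIRST_STERILE]
_SR = STATE_INDEX[MatingState.STERILE_RESCUED]


# ---------------------------------------------------------------------------
# population container
# ---------------------------------------------------------------------------

@dataclass
class Population:
    """Counts per equivalence class.

    ``females[age, state]`` and ``males[age]`` hold wild individuals by
    absolute age in weeks (juveniles occupy the ages below the adult
    emergence age; juvenile females sit in the VIRGIN column).  Released
    sterile males are kept per strain in ``released[name][age]`` with their
    mating fitness in ``released_fitness[name]``.
    """

    females: np.ndarray
    males: np.ndarray
    released: dict[str, np.ndarray] = field(default_factory=dict)
    released_fitness: dict[str, float] = field(default_factory=dict)
    larval_duration: int = 1
    pupal_duration: int = 2

    @classmethod
    def empty(cls, config: SimConfig) -> "Population":
        return cls(
            females=np.zeros((len(config.female_age_survival), 4), dtype=np.int64),
            males=np.zeros(len(config.male_age_survival), dtype=np.int64),
            larval_duration=config.larval_duration,
            pupal_duration=config.pupal_duration,
        )

    @property
    def emergence_age(self) -> int:
        return self.larval_duration + self.pupal_duration

    # --- wild census -------------------------------------------------------
    @property
    def adult_wild_females(self) -> int:
        return int(self.females[self.emergence_age:, :].sum())

    @property
    def adult_wild_males(self) -> int:
        return int(self.males[self.emergence_age:].sum())

    @property
    def wild_larvae(self) -> int:
        d = self.larval_duration
        return int(self.females[:d, :].sum() + self.males[:d].sum())

    @property
    def wild_pupae(self) -> int:
        d, e = self.larval_duration, self.emergence_age
        return int(self.females[d:e, :].sum() + self.males[d:e].sum())

    @property
    def total_wild(self) -> int:
        return int(self.females.sum() + self.males.sum())

    @property
    def released_males_alive(self) -> int:
        return int(sum(arr.sum() for arr in self.released.values()))

    def add_released(self, name: str, fitness: float, count: int) -> None:
        """Inject ``count`` sterile adult males of a strain at emergence age."""
        if count < 0:
            raise InvalidParameterError("release count must be non-negative")
        if name not in self.released:
            self.released[name] = np.zeros_like(self.males)
            self.released_fitness[name] = float(fitness)
        elif self.released_fitness[name] != fitness:
            raise InvalidParameterError(
                f"strain {name!r} already present with different fitness"
            )
        self.released[name][self.emergence_age] += int(count)

    def insert_newborns(self, n_females: int, n_males: int) -> None:
        """Add this week's competition survivors to the population.

        A clutch spends the week it was laid as age-0 larvae (already thinned
        by :func:`apply_larval_competition`), so survivors enter the census at
        age 1 after the weekly age shift and emerge as adults exactly
        ``larval_duration + pupal_duration`` weeks after oviposition.
        """
        self.females[1, _V] += int(n_females)
        self.males[1] += int(n_males)

    def copy(self) -> "Population":
        return Population(
            females=self.females.copy(),
            males=self.males.copy(),
            released={k: v.copy() for k, v in self.released.items()},
            released_fitness=dict(self.released_fitness),
            larval_duration=self.larval_duration,
            pupal_duration=self.pupal_duration,
        )


# ---------------------------------------------------------------------------
# density dependence and survival schedules
# ---------------------------------------------------------------------------

def larval_survival_rate(
    n_larvae: float,
    expected_larvae: float,
    beta: float,
    base_larval_survival: float,
) -> float:
    """Beverton-Holt weekly larval survival probability.

    ``base_larval_survival * beta / ((beta - 1) * f + 1)`` with competition
    factor ``f = n_larvae / expected_larvae``: equal to the base rate at
    carrying-capacity density (f = 1) and ``beta``-fold higher in the
    low-density limit (f = 0), declining monotonically in between.
    """
    if expected_larvae <= 0:
        raise InvalidParameterError("expected_larvae must be positive")
    if beta < 1.0:
        raise InvalidParameterError("beta must be >= 1")
    if n_larvae < 0:
        raise InvalidParameterError("n_larvae must be non-negative")
    f = n_larvae / expected_larvae
    return base_larval_survival * beta / ((beta - 1.0) * f + 1.0)


def age_survival_prob(age: int, sex: str, config: SimConfig) -> float:
    """Conditional age-based weekly survival at ``age`` for ``sex``.

    Ages beyond the end of the schedule return 0 (nobody reaches them).
    """
    if age < 0:
        raise InvalidParameterError("age must be non-negative")
    if sex == "male":
        sched = config.male_age_survival
    elif sex == "female":
        sched = config.female_age_survival
    else:
        raise InvalidParameterError(f"sex must be 'male' or 'female', got {sex!r}")
    return sched[age] if age < len(sched) else 0.0


# ---------------------------------------------------------------------------
# mating
# ---------------------------------------------------------------------------

class MaleGroup(NamedTuple):
    """A pool of exchangeable adult males competing for matings."""
    name: str
    count: int
    mating_fitness: float
    sterile: bool


def male_groups(pop: Population) -> list[MaleGroup]:
    """Adult male pools currently competing for matings (wild first)."""
    groups = [MaleGroup("wild", pop.adult_wild_males, 1.0, False)]
    for name in sorted(pop.released):
        groups.append(
            MaleGroup(
                name,
                int(pop.released[name][pop.emergence_age:].sum()),
                pop.released_fitness[name],
                True,
            )
        )
    return groups


def sterile_mating_probability(groups: Iterable[MaleGroup]) -> float | None:
    """Probability a fitness-weighted random mate is sterile.

    Returns ``None`` when no males are present (no matings occur).
    """
    total = 0.0
    sterile = 0.0
    for g in groups:
        w = g.count * g.mating_fitness
        total += w
        if g.sterile:
            sterile += w
    if total <= 0.0:
        return None
    return sterile / total


def select_mates(
    n_matings: int,
    groups: list[MaleGroup],
    rng: np.random.Generator,
) -> np.ndarray:
    """Assign ``n_matings`` females a mate each, sampled with replacement
    with probability proportional to ``count * mating_fitness``.

    Returns the number of matings won by each group (multinomial; the
    exchangeable-class equivalent of drawing one male per female).  An empty
    male pool yields all zeros: no matings occur.
    """
    if n_matings < 0:
        raise InvalidParameterError("n_matings must be non-negative")
    weights = np.array([g.count * g.mating_fitness for g in groups], dtype=float)
    total = weights.sum()
    if total <= 0.0 or n_matings == 0:
        return np.zeros(len(groups), dtype=np.int64)
    return rng.multinomial(n_matings, weights / total).astype(np.int64)


class MatingRoundSummary(NamedTuple):
    n_virgin_matings: int
    n_rematings: int
    n_first_sterile: int
    n_rescued: int
    n_mated_females: int          # mated females present before the round
    sterile_probability: float | None


def weekly_mating_round(
    pop: Population, config: SimConfig, rng: np.random.Generator
) -> MatingRoundSummary:
    """One week of mating.

    Every virgin adult female mates once (if any males exist); every
    previously mated female remates with probability ``remating_prob``.
    Mate identity only matters through whether the male is sterile, so each
    mating applies the two-outcome marginal of the fitness-weighted
    assignment in :func:`select_mates`.
    """
    groups = male_groups(pop)
    p_sterile = sterile_mating_probability(groups)
    ea = pop.emergence_age
    adults = pop.females[ea:, :]
    n_mated = int(adults[:, [_FF, _FS, _SR]].sum())
    if p_sterile is None:
        return MatingRoundSummary(0, 0, 0, 0, n_mated, None)

    # virgins: first mating decides fertile vs sterile lineage of the sperm
    n_virgin = adults[:, _V].copy()
    first_sterile = rng.binomial(n_virgin, p_sterile)
    adults[:, _FS] += first_sterile
    adults[:, _FF] += n_virgin - first_sterile
    adults[:, _V] = 0

    # remating: only FIRST_STERILE females can change state (rescue by a
    # fertile mate); remating is still drawn for the other mated states so
    # the remating frequency is observable for any mated female.
    rem_ff = rng.binomial(adults[:, _FF], config.remating_prob)
    rem_sr = rng.binomial(adults[:, _SR], config.remating_prob)
    rem_fs = rng.binomial(adults[:, _FS], config.remating_prob)
    rescued = rng.binomial(rem_fs, 1.0 - p_sterile)
    adults[:, _FS] -= rescued
    adults[:, _SR] += rescued

    return MatingRoundSummary(
        n_virgin_matings=int(n_virgin.sum()),
        n_rematings=int(rem_ff.sum() + rem_sr.sum() + rem_fs.sum()),
        n_first_sterile=int(first_sterile.sum()),
        n_rescued=int(rescued.sum()),
        n_mated_females=n_mated,
        sterile_probability=p_sterile,
    )


# ---------------------------------------------------------------------------
# reproduction and larval competition
# ---------------------------------------------------------------------------

class ReproductionSummary(NamedTuple):
    eggs: int
    n_fertile_clutches: int
    n_rescued_clutches: int
    n_eligible_fertile: int
    n_eligible_rescued: int


def weekly_reproduction(
    pop: Population, config: SimConfig, rng: np.random.Generator
) -> ReproductionSummary:
    """Clutch production for the week; returns the egg count entering the
    larval pool.

    Females reproduce from their second adult week on.  A FIRST_FERTILE
    female produces a clutch every week; a STERILE_RESCUED female produces
    one with probability ``rescue_fertility`` (a Bernoulli gate on the whole
    clutch, not a halved clutch size); virgin and FIRST_STERILE females
    produce nothing.  Realized clutch sizes are iid Poisson, so the weekly
    total is Poisson with mean ``poisson_mean_eggs`` times the clutch count.
    """
    first_repro_age = pop.emergence_age + 1
    n_ff = int(pop.females[first_repro_age:, _FF].sum())
    n_sr = int(pop.females[first_repro_age:, _SR].sum())
    rescued_clutches = int(rng.binomial(n_sr, config.rescue_fertility))
    clutches = n_ff + rescued_clutches
    eggs = int(rng.poisson(config.poisson_mean_eggs * clutches))
    return ReproductionSummary(eggs, n_ff, rescued_clutches, n_ff, n_sr)


def apply_larval_competition(
    egg_count: int, config: SimConfig, rng: np.random.Generator
) -> int:
    """Density-dependent thinning of the week's clutches.

    Survivors are Binomial(egg_count, rate) with the Beverton-Holt rate
    evaluated at the clutch cohort's own density.
    """
    if egg_count < 0:
        raise InvalidParameterError("egg_count must be non-negative")
    if config.expected_larvae is None:
        raise InvalidParameterError(
            "expected_larvae is not set; run calibration first"
        )
    if egg_count == 0:
        return 0
    rate = larval_survival_rate(
        egg_count, config.expected_larvae, config.beta, config.base_larval_survival
    )
    return int(rng.binomial(egg_count, min(rate, 1.0)))


# ---------------------------------------------------------------------------
# mortality, aging and stage transitions
# ---------------------------------------------------------------------------

class MortalitySummary(NamedTuple):
    female_deaths: int
    male_deaths: int
    released_deaths: int


def _survival_vector(schedule, config: SimConfig) -> np.ndarray:
    """Per-age weekly survival: juveniles at 1, adults at background x age."""
    p = np.asarray(schedule, dtype=float) * config.adult_background_survival
    p[: config.adult_emergence_age] = 1.0
    return p


def apply_mortality_and_aging(
    pop: Population, config: SimConfig, rng: np.random.Generator
) -> MortalitySummary:
    """End-of-week mortality, then advance every survivor one week of age.

    Juveniles survive the age step with certainty (their only mortality is
    larval competition); adults survive with background times age-schedule
    probability.  Stage transitions are implied by age: survivors crossing
    the emergence age become adults with zero completed adult weeks.  The
    terminal schedule entries are 0, so nobody outlives the schedules.
    """
    p_f = _survival_vector(config.female_age_survival, config)
    before_f = int(pop.females.sum())
    surv_f = rng.binomial(pop.females, p_f[:, None])
    pop.females[:] = 0
    pop.females[1:, :] = surv_f[:-1, :]

    p_m = _survival_vector(config.male_age_survival, config)
    before_m = int(pop.males.sum())
    surv_m = rng.binomial(pop.males, p_m)
    pop.males[:] = 0
    pop.males[1:] = surv_m[:-1]

    rel_deaths = 0
    for arr in pop.released.values():
        before = int(arr.sum())
        surv = rng.binomial(arr, p_m)
        arr[:] = 0
        arr[1:] = surv[:-1]
        rel_deaths += before - int(surv.sum())

    return MortalitySummary(
        female_deaths=before_f - int(surv_f.sum()),
        male_deaths=before_m - int(surv_m.sum()),
        released_deaths=rel_deaths,
    )


# ---------------------------------------------------------------------------
# full weekly step
# ---------------------------------------------------------------------------

class WeekRecord(NamedTuple):
    eggs_laid: int
    larvae_surviving: int
    adult_wild_females: int
    adult_wild_males: int
    released_males: int
    wild_larvae: int
    wild_pupae: int
    n_rematings: int
    n_mated_females: int
    sterile_probability: float | None


def step_week(
    pop: Population,
    config: SimConfig,
    rng: np.random.Generator,
    release_cohorts: Iterable = (),
) -> WeekRecord:
    """Advance the population one week through the full event sequence.

    ``release_cohorts`` are objects with ``count``, ``name`` and
    ``mating_fitness`` attributes (see ``release.make_release_cohort``);
    they are injected before mating so released males compete immediately.
    """
    for cohort in release_cohorts:
        pop.add_released(cohort.name, cohort.mating_fitness, cohort.count)

    mate = weekly_mating_round(pop, config, rng)
    repro = weekly_reproduction(pop, config, rng)
    older_larvae = pop.wild_larvae  # previous clutches still larval this week
    survivors = apply_larval_competition(repro.eggs, config, rng)
    newborn_f = int(rng.binomial(survivors, 0.5))
    newborn_m = survivors - newborn_f
    apply_mortality_and_aging(pop, config, rng)
    pop.insert_newborns(newborn_f, newborn_m)

    return WeekRecord(
        eggs_laid=repro.eggs,
        larvae_surviving=survivors,
        adult_wild_females=pop.adult_wild_females,
        adult_wild_males=pop.adult_wild_males,
        released_males=pop.released_males_alive,
        wild_larvae=survivors + older_larvae,
        wild_pupae=pop.wild_pupae,
        n_rematings=mate.n_rematings,
        n_mated_females=mate.n_mated_females,
        sterile_probability=mate.sterile_probability,
    )
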