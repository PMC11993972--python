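"""Release systems: strain profiles, effective release sizes, schedules.

Five named systems are compared at equal rearing effort.  A unit of effort
is the food needed to rear one standard-SIT male.  Sex-conversion strains
(CRISPR *transformer* knockout) convert part of their XX progeny into
fertile phenotypic males, raising male output per unit food; a strain with
reduced rearing survival lowers it.  Radiation-sterilised males carry a
mating-success cost (relative fitness 0.83); genetically sterilised (pgSIT)
males are assumed cost-free.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InvalidParameterError


def effective_release_multiplier(
    rearing_survival_rel: float, xx_male_fraction: float
) -> float:
    """Effective males released per unit standard-SIT rearing effort.

    Half of reared individuals are XX; converting a fraction of those into
    males raises male output from 0.5 to ``0.5 * (1 + xx_male_fraction)``
    per individual reared, scaled by the strain's relative rearing survival:
    ``survival * (1 + xx_male_fraction)``.
    """
    if not (0.0 <= rearing_survival_rel <= 1.0):
        raise InvalidParameterError(
            f"rearing_survival_rel must be in [0, 1], got {rearing_survival_rel!r}"
        )
    if not (0.0 <= xx_male_fraction <= 1.0):
        raise InvalidParameterError(
            f"xx_male_fraction must be in [0, 1], got {xx_male_fraction!r}"
        )
    return rearing_survival_rel * (1.0 + xx_male_fraction)


_DEFAULT_FITNESS = {"radiation": 0.83, "genetic": 1.0}


@dataclass(frozen=True)
class StrainProfile:
    """A release system: how males are sterilised and how many effective
    males one unit of rearing effort yields."""

    name: str
    sterilisation: str                 # "radiation" | "genetic"
    male_mating_fitness: float
    rearing_survival_rel: float = 1.0
    xx_male_fraction: float = 0.0
    release_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.sterilisation not in _DEFAULT_FITNESS:
            raise InvalidParameterError(
                f"sterilisation must be 'radiation' or 'genetic', got "
                f"{self.sterilisation!r}"
            )
        if not (0.0 < self.male_mating_fitness <= 1.0):
            raise InvalidParameterError("male_mating_fitness must be in (0, 1]")
        if self.release_multiplier < self.rearing_survival_rel:
            raise InvalidParameterError(
                "release_multiplier cannot fall below relative rearing survival"
            )


def strain_profile(
    name: str,
    sterilisation: str,
    male_mating_fitness: float | None = None,
    rearing_survival_rel: float = 1.0,
    xx_male_fraction: float = 0.0,
    release_multiplier: float | None = None,
) -> StrainProfile:
    """Build a profile, filling sterilisation-mode defaults.

    Mating fitness defaults to 0.83 for radiation and 1.0 for genetic
    sterilisation; the release multiplier defaults to
    :func:`effective_release_multiplier` of the rearing parameters.
    """
    if sterilisation not in _DEFAULT_FITNESS:
        raise InvalidParameterError(
            f"sterilisation must be 'radiation' or 'genetic', got {sterilisation!r}"
        )
    if male_mating_fitness is None:
        male_mating_fitness = _DEFAULT_FITNESS[sterilisation]
    if release_multiplier is None:
        release_multiplier = effective_release_multiplier(
            rearing_survival_rel, xx_male_fraction
        )
    return StrainProfile(
        name=name,
        sterilisation=sterilisation,
        male_mating_fitness=male_mating_fitness,
        rearing_survival_rel=rearing_survival_rel,
        xx_male_fraction=xx_male_fraction,
        release_multiplier=release_multiplier,
    )


def _builtin() -> dict[str, StrainProfile]:
    # DmPub.2's multiplier is taken as the stated 1.1% increase; its XX-male
    # fraction is back-solved from that multiplier.
    return {
        "standard_SIT": strain_profile("standard_SIT", "radiation"),
        "DmPub2_radiation": strain_profile(
            "DmPub2_radiation", "radiation", xx_male_fraction=0.011
        ),
        "DmPub2_pgSIT": strain_profile(
            "DmPub2_pgSIT", "genetic", xx_male_fraction=0.011
        ),
        "CcPub1_radiation": strain_profile(
            "CcPub1_radiation",
            "radiation",
            rearing_survival_rel=0.85,
            xx_male_fraction=0.35,
        ),
        "CcPub1_pgSIT": strain_profile(
            "CcPub1_pgSIT",
            "genetic",
            rearing_survival_rel=0.85,
            xx_male_fraction=0.35,
        ),
    }


#: The five release systems compared in the study.
BUILTIN_PROFILES: dict[str, StrainProfile] = _builtin()


def get_profile(name: str) -> StrainProfile:
    try:
        return BUILTIN_PROFILES[name]
    except KeyError:
        raise InvalidParameterError(
            f"unknown strain profile {name!r}; known: {sorted(BUILTIN_PROFILES)}"
        ) from None


@dataclass(frozen=True)
class ReleaseSchedule:
    """Weekly release effort and cadence.

    ``release_ratio`` is effort per week as a fraction of the equilibrium
    wild adult male count.  With an interval of n weeks, each release is n
    times the weekly amount, so total effort over any horizon is independent
    of the interval (up to rounding).
    """

    release_ratio: float
    interval_weeks: int = 1
    start_week: int = 1

    def __post_init__(self) -> None:
        if self.release_ratio < 0:
            raise InvalidParameterError("release_ratio must be non-negative")
        if self.interval_weeks < 1:
            raise InvalidParameterError("interval_weeks must be at least 1")
        if self.start_week < 1:
            raise InvalidParameterError("start_week must be at least 1")

    def is_release_week(self, week: int) -> bool:
        return week >= self.start_week and (
            (week - self.start_week) % self.interval_weeks == 0
        )


def weekly_release_count(
    schedule: ReleaseSchedule,
    week: int,
    equilibrium_wild_males: float,
    profile: StrainProfile,
) -> int:
    """Males released in a given release-phase week (0 off-schedule).

    On release weeks the count is ratio x equilibrium wild males x the
    strain's effective release multiplier x interval, rounded half-up.
    """
    if equilibrium_wild_males <= 0:
        raise InvalidParameterError("equilibrium_wild_males must be positive")
    if not schedule.is_release_week(week):
        return 0
    raw = (
        schedule.release_ratio
        * equilibrium_wild_males
        * profile.release_multiplier
        * schedule.interval_weeks
    )
    return int(math.floor(raw + 0.5))


@dataclass(frozen=True)
class ReleaseCohort:
    """A batch of sterile adult males entering the population this week."""

    count: int
    profile: StrainProfile

    @property
    def name(self) -> str:
        return self.profile.name

    @property
    def mating_fitness(self) -> float:
        return self.profile.male_mating_fitness

    @property
    def sterile(self) -> bool:
        return True


def make_release_cohort(count: int, profile: StrainProfile) -> ReleaseCohort:
    """Cohort of ``count`` sterile adult males of a strain, entering at the
    adult emergence age with zero completed adult weeks."""
    if count < 0:
        raise InvalidParameterError("count must be non-negative")
    return ReleaseCohort(count=int(count), profile=profile)
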