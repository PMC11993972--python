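"""Simulation configuration: demographic rates, schedules and run control.

The defaults describe a panmictic *Ceratitis capitata* (medfly) population
with overlapping generations on a weekly time step: a one-week larval stage
subject to density-dependent (Beverton-Holt) competition, a two-week pupal
stage with no additional mortality, and adults whose weekly survival is the
product of a background rate (predation and other unmodelled causes) and an
age-conditional schedule that forces a maximum lifespan of 19 weeks for
males and 13 weeks for females.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

from .errors import ConfigError


def _declining_schedule(n_ones: int, n_decline: int) -> tuple[float, ...]:
    """Conditional weekly survival: ``n_ones`` weeks at 1, then k/(k+1) for
    k = n_decline..1, ending in 0.  The declining tail produces a linear
    decrease in the number of survivors week over week."""
    tail = [k / (k + 1.0) for k in range(n_decline, 0, -1)]
    return tuple([1.0] * n_ones + tail + [0.0])


#: Conditional weekly survival probabilities for males, indexed by age 0..18.
#: No male survives past his nineteenth week.
MALE_AGE_SURVIVAL: tuple[float, ...] = _declining_schedule(5, 13)

#: Conditional weekly survival probabilities for females, indexed by age 0..12.
#: No female survives past her thirteenth week.
FEMALE_AGE_SURVIVAL: tuple[float, ...] = _declining_schedule(5, 7)


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ConfigError(f"{name} must be a probability in [0, 1], got {value!r}")


@dataclass(frozen=True)
class SimConfig:
    """All demographic, mating, density-dependence and run-control parameters.

    Parameters
    ----------
    beta
        Low-density growth rate of the Beverton-Holt larval survival term
        (dimensionless).
    base_larval_survival
        Larval survival probability at carrying-capacity density (competition
        factor f = 1).
    poisson_mean_eggs
        Mean of the Poisson clutch-size distribution (eggs per reproducing
        female per week).
    remating_prob
        Weekly probability that an already-mated female remates.
    rescue_fertility
        Weekly clutch probability for a female whose first mate was sterile
        and who later remated with a fertile male (sperm-precedence rescue).
    adult_background_survival
        Weekly adult survival from causes other than age (applied on top of
        the age schedules; juveniles are exempt).
    male_age_survival, female_age_survival
        Conditional weekly survival schedules indexed by age in weeks.
    larval_duration, pupal_duration
        Stage durations in weeks; adults emerge at age
        ``larval_duration + pupal_duration``.
    init_adult_females
        Target equilibrium adult female count at ``scale_factor`` 1.
    scale_factor
        Linear population scaling for desk-scale runs; scales absolute counts
        (initial population, expected larvae, releases) and no per-capita rate.
    burn_in_weeks, horizon_weeks
        Pre-release equilibration length and release-phase length.
    expected_larvae
        Weekly larval count at which the competition factor equals 1; usually
        left ``None`` and filled in by calibration.
    seed
        Default RNG seed for runs that are not given one explicitly.
    """

    beta: float = 10.0
    base_larval_survival: float = 0.3344 / 9.373
    poisson_mean_eggs: float = 9.37
    remating_prob: float = 1.0 / 3.0
    rescue_fertility: float = 0.5
    adult_background_survival: float = 0.9
    male_age_survival: tuple[float, ...] = MALE_AGE_SURVIVAL
    female_age_survival: tuple[float, ...] = FEMALE_AGE_SURVIVAL
    larval_duration: int = 1
    pupal_duration: int = 2
    init_adult_females: float = 50_000.0
    scale_factor: float = 1.0
    burn_in_weeks: int = 50
    horizon_weeks: int = 100
    expected_larvae: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beta < 1.0:
            raise ConfigError(f"beta must be >= 1, got {self.beta!r}")
        _check_prob("base_larval_survival", self.base_larval_survival)
        if self.poisson_mean_eggs <= 0:
            raise ConfigError("poisson_mean_eggs must be positive")
        _check_prob("remating_prob", self.remating_prob)
        _check_prob("rescue_fertility", self.rescue_fertility)
        _check_prob("adult_background_survival", self.adult_background_survival)
        for name in ("male_age_survival", "female_age_survival"):
            sched = getattr(self, name)
            if len(sched) < 2:
                raise ConfigError(f"{name} must have at least two entries")
            for i, p in enumerate(sched):
                _check_prob(f"{name}[{i}]", p)
            if sched[-1] != 0.0:
                raise ConfigError(f"{name} must end in 0 (a hard maximum age)")
            head = sched[: min(5, len(sched) - 1)]
            if any(p != 1.0 for p in head):
                raise ConfigError(
                    f"{name} must equal 1 over the first five weeks "
                    "(juvenile mortality is represented at larval competition)"
                )
        if self.larval_duration < 1 or self.pupal_duration < 1:
            raise ConfigError("stage durations must be at least one week")
        emergence = self.larval_duration + self.pupal_duration
        if emergence >= len(self.female_age_survival):
            raise ConfigError(
                "female_age_survival too short for the juvenile stage durations"
            )
        if self.init_adult_females <= 0:
            raise ConfigError("init_adult_females must be positive")
        if self.scale_factor <= 0:
            raise ConfigError("scale_factor must be positive")
        if self.burn_in_weeks < 1:
            raise ConfigError("burn_in_weeks must be at least 1")
        if self.horizon_weeks < 1:
            raise ConfigError("horizon_weeks must be at least 1")
        if self.expected_larvae is not None and self.expected_larvae <= 0:
            raise ConfigError("expected_larvae must be positive when given")

    @property
    def adult_emergence_age(self) -> int:
        """Age in weeks at which a fly becomes an adult."""
        return self.larval_duration + self.pupal_duration

    @property
    def scaled_init_females(self) -> float:
        return self.init_adult_females * self.scale_factor

    def replace(self, **changes) -> "SimConfig":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["male_age_survival"] = list(d["male_age_survival"])
        d["female_age_survival"] = list(d["female_age_survival"])
        return d

    @classmethod
    def field_names(cls) -> set[str]:
        return {f.name for f in dataclasses.fields(cls)}

    @classmethod
    def from_dict(cls, data: dict) -> "SimConfig":
        unknown = set(data) - cls.field_names()
        if unknown:
            raise ConfigError(f"unknown simulation keys: {sorted(unknown)}")
        kwargs = dict(data)
        for name in ("male_age_survival", "female_age_survival"):
            if name in kwargs:
                kwargs[name] = tuple(kwargs[name])
        return cls(**kwargs)
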