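"""Sperm-precedence mating state machine.

Medfly females are polyandrous but use sperm from their first mate
preferentially.  The model collapses a female's mating history into four
states: virgin, first mate fertile (full fertility, absorbing), first mate
sterile (no offspring), and sterile-then-rescued (a later fertile mate
restores partial fertility).  Transitions are monotone: fertility gained
through a first fertile mating is never lost, and a sterile first mating is
at best partially rescued.
"""

from __future__ import annotations

from enum import Enum

from .errors import InvalidParameterError


class MatingState(Enum):
    VIRGIN = "virgin"
    FIRST_FERTILE = "first_fertile"
    FIRST_STERILE = "first_sterile"
    STERILE_RESCUED = "sterile_rescued"


#: Column order used by the vectorized population arrays.
STATE_ORDER: tuple[MatingState, ...] = (
    MatingState.VIRGIN,
    MatingState.FIRST_FERTILE,
    MatingState.FIRST_STERILE,
    MatingState.STERILE_RESCUED,
)
STATE_INDEX: dict[MatingState, int] = {s: i for i, s in enumerate(STATE_ORDER)}
N_STATES = len(STATE_ORDER)


def fertility(state: MatingState, rescue_fertility: float = 0.5) -> float:
    """Weekly clutch probability implied by a mating state.

    A virgin or sterile-first-mated female produces nothing; a female whose
    first mate was fertile produces a clutch every eligible week; a rescued
    female produces a clutch with probability ``rescue_fertility``.
    """
    if state is MatingState.FIRST_FERTILE:
        return 1.0
    if state is MatingState.STERILE_RESCUED:
        return rescue_fertility
    return 0.0


def update_mating_state(current: MatingState, male_is_sterile: bool) -> MatingState:
    """State after one mating with a sterile or fertile male.

    First-male sperm precedence: a fertile first mating absorbs everything
    after it; a sterile first mating can only be partially rescued by a later
    fertile mate, and the rescued state is itself absorbing.
    """
    if not isinstance(current, MatingState):
        raise InvalidParameterError(f"not a MatingState: {current!r}")
    if current is MatingState.VIRGIN:
        return MatingState.FIRST_STERILE if male_is_sterile else MatingState.FIRST_FERTILE
    if current is MatingState.FIRST_STERILE and not male_is_sterile:
        return MatingState.STERILE_RESCUED
    return current
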