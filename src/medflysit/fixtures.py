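"""Named scaled-down scenarios for tests and desk runs.

All scenarios share every per-capita rate; only absolute counts scale, so
the per-capita dynamics are identical and only demographic noise differs.
"""

from __future__ import annotations

from .config import SimConfig
from .errors import InvalidParameterError

#: Scenario name -> linear population scale.
SCENARIO_SCALES: dict[str, float] = {
    "micro": 0.002,   # ~100 adult females: fast unit tests, noisy
    "desk": 0.1,      # ~5,000 adult females: desk-scale experiments
    "paper": 1.0,     # 50,000 adult females: full scale
}


def make_fixture_scenario(name: str, **overrides) -> SimConfig:
    """Deterministic small scenario configurations by name.

    ``overrides`` are applied on top of the scenario's scale (e.g. a seed or
    a shorter burn-in for unit tests).
    """
    try:
        scale = SCENARIO_SCALES[name]
    except KeyError:
        raise InvalidParameterError(
            f"unknown fixture scenario {name!r}; known: {sorted(SCENARIO_SCALES)}"
        ) from None
    return SimConfig(scale_factor=scale).replace(**overrides)
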