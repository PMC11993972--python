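"""Configuration loading, result serialization and run manifests.

The run configuration is a single YAML file with up to three sections:

.. code-block:: yaml

    simulation:         # any SimConfig field; omitted fields use defaults
      scale_factor: 0.1
      seed: 7
    profile: CcPub1_pgSIT        # built-in name, or an inline mapping
    schedule:
      release_ratio: 1.0
      interval_weeks: 1

Results are written as plain CSV (one trajectory file per run plus optional
grid tables) and JSON summaries, all referenced from a manifest that is
sufficient to reproduce every file bit-identically.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass, field
from importlib import metadata
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd
import yaml

from .config import SimConfig
from .errors import ConfigError
from .release import ReleaseSchedule, StrainProfile, get_profile, strain_profile
from .simulate import Trajectory

_TOP_LEVEL_KEYS = {"simulation", "profile", "schedule"}
_PROFILE_KEYS = {
    "name", "sterilisation", "male_mating_fitness",
    "rearing_survival_rel", "xx_male_fraction", "release_multiplier",
}
_SCHEDULE_KEYS = {"release_ratio", "interval_weeks", "start_week"}


@dataclass(frozen=True)
class LoadedConfig:
    config: SimConfig
    profile: Optional[StrainProfile]
    schedule: Optional[ReleaseSchedule]


def _parse_profile(spec) -> StrainProfile:
    if isinstance(spec, str):
        return get_profile(spec)
    if not isinstance(spec, dict):
        raise ConfigError("profile must be a built-in name or a mapping")
    unknown = set(spec) - _PROFILE_KEYS
    if unknown:
        raise ConfigError(f"unknown profile keys: {sorted(unknown)}")
    missing = {"name", "sterilisation"} - set(spec)
    if missing:
        raise ConfigError(f"profile is missing required keys: {sorted(missing)}")
    try:
        return strain_profile(**spec)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid profile: {exc}") from exc


def _parse_schedule(spec) -> ReleaseSchedule:
    if not isinstance(spec, dict):
        raise ConfigError("schedule must be a mapping")
    unknown = set(spec) - _SCHEDULE_KEYS
    if unknown:
        raise ConfigError(f"unknown schedule keys: {sorted(unknown)}")
    if "release_ratio" not in spec:
        raise ConfigError("schedule is missing required key 'release_ratio'")
    try:
        return ReleaseSchedule(**spec)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid schedule: {exc}") from exc


def load_config(path) -> LoadedConfig:
    """Parse and validate a YAML run configuration.

    An empty file yields the full default parameter set and no release
    program.  Validation errors name the offending key.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    data = yaml.safe_load(path.read_text()) or {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(data) - _TOP_LEVEL_KEYS
    if unknown:
        raise ConfigError(
            f"unknown top-level keys: {sorted(unknown)} "
            f"(expected {sorted(_TOP_LEVEL_KEYS)})"
        )
    sim = data.get("simulation") or {}
    if not isinstance(sim, dict):
        raise ConfigError("'simulation' must be a mapping")
    config = SimConfig.from_dict(sim)
    profile = _parse_profile(data["profile"]) if "profile" in data else None
    schedule = _parse_schedule(data["schedule"]) if "schedule" in data else None
    return LoadedConfig(config=config, profile=profile, schedule=schedule)


# ---------------------------------------------------------------------------
# results + manifest
# ---------------------------------------------------------------------------

def _package_version() -> str:
    try:
        return metadata.version("medfly-sit")
    except metadata.PackageNotFoundError:   # pragma: no cover
        return "unknown"


@dataclass
class RunManifest:
    """Reproducibility record for a set of emitted result files."""

    config: dict
    seeds: dict
    profile: Optional[dict] = None
    schedule: Optional[dict] = None
    software_version: str = field(default_factory=_package_version)
    started: str = ""
    finished: str = ""
    outputs: dict = field(default_factory=dict)

    @staticmethod
    def now() -> str:
        return datetime.datetime.now(datetime.timezone.utc).isoformat()

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        return cls(**json.loads(text))


def trajectory_csv(trajectory: Trajectory) -> str:
    return trajectory.frame.to_csv(index=False)


def read_trajectory_csv(path) -> pd.DataFrame:
    """Read a written trajectory back; equal to the in-memory frame."""
    return pd.read_csv(path, dtype={"phase": str}).astype(
        {"eliminated": bool}
    )


def write_results(
    trajectories: Mapping[str, Trajectory],
    tables: Mapping[str, pd.DataFrame],
    manifest: RunManifest,
    out_dir,
) -> dict[str, Path]:
    """Write trajectory CSVs, grid tables and the manifest to ``out_dir``.

    Returns the mapping of logical names to file paths; every file is
    recorded in the manifest's ``outputs``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, traj in trajectories.items():
        p = out_dir / f"trajectory_{name}.csv"
        p.write_text(trajectory_csv(traj))
        written[f"trajectory_{name}"] = p
    for name, table in tables.items():
        p = out_dir / f"{name}.csv"
        p.write_text(table.to_csv(index=False))
        written[name] = p
    manifest.outputs = {k: str(p.name) for k, p in written.items()}
    manifest.finished = RunManifest.now()
    mp = out_dir / "manifest.json"
    mp.write_text(manifest.to_json())
    written["manifest"] = mp
    return written
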