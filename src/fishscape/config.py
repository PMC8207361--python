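"""YAML configuration schema for single runs and factorial grids.

An empty config means the full study defaults: 15 years of 40 movement
steps, 900 initial fish, and the factorial levels 2 preference modes x
6 fishing mortalities x 2 landscapes x 6 carrying capacities.  Levels
outside those schedules trigger a warning naming the schedule (or a
validation error for impossible values); ``allow_off_schedule: true``
silences the warnings for sensitivity runs.
"""

from __future__ import annotations

import warnings
from dataclasses import fields

import yaml

from .demography import FISHING_SCHEDULE
from .engine import CARRYING_CAPACITIES, GridLevels, SimConfig

__all__ = ["load_config", "sim_config_from_mapping", "grid_levels_from_mapping"]

_SIM_KEYS = {f.name for f in fields(SimConfig)}
_GRID_KEYS = {
    "preferences",
    "fishing_mortalities",
    "landscapes",
    "carrying_capacities",
}
_META_KEYS = {"allow_off_schedule"}


def _warn_off_schedule(values, schedule, what: str, allow: bool) -> None:
    off = [v for v in values if v not in schedule]
    if off and not allow:
        warnings.warn(
            f"{what} {off} outside the study schedule {tuple(schedule)}",
            stacklevel=3,
        )


def sim_config_from_mapping(mapping: dict) -> SimConfig:
    """Validated single-run config; unknown keys are an error."""
    mapping = dict(mapping or {})
    allow = bool(mapping.pop("allow_off_schedule", False))
    unknown = set(mapping) - _SIM_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    config = SimConfig(**mapping)
    _warn_off_schedule(
        [config.fishing_mortality], FISHING_SCHEDULE, "fishing mortality", allow
    )
    _warn_off_schedule(
        [config.carrying_capacity], CARRYING_CAPACITIES, "carrying capacity", allow
    )
    return config


def grid_levels_from_mapping(mapping: dict) -> GridLevels:
    """Validated factorial levels; unspecified factors keep study defaults."""
    mapping = dict(mapping or {})
    allow = bool(mapping.pop("allow_off_schedule", False))
    unknown = set(mapping) - _GRID_KEYS
    if unknown:
        raise ValueError(f"unknown grid config keys: {sorted(unknown)}")
    kwargs = {k: tuple(v) for k, v in mapping.items()}
    levels = GridLevels(**kwargs)
    _warn_off_schedule(
        levels.fishing_mortalities, FISHING_SCHEDULE, "fishing mortality", allow
    )
    _warn_off_schedule(
        levels.carrying_capacities, CARRYING_CAPACITIES, "carrying capacity", allow
    )
    return levels


def load_config(path) -> SimConfig | GridLevels:
    """Parse a YAML config file.

    A mapping with a top-level ``grid:`` key (or any of the factor-level
    keys) yields :class:`GridLevels`; otherwise a :class:`SimConfig` with
    full study defaults for unset keys.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    if "grid" in raw:
        return grid_levels_from_mapping(raw["grid"])
    if set(raw) & _GRID_KEYS:
        return grid_levels_from_mapping(raw)
    return sim_config_from_mapping(raw)
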