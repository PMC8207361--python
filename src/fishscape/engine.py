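"""The individual-based simulation engine.

Each simulated year consists of 40 synchronous movement steps followed by
one demographic update.  At every step each fish compares the realized
suitability of its current cell with that of one uniformly chosen Moore
neighbor, computed from the occupancy snapshot taken at the start of the
step, and moves only on a strict improvement:

    R(c, i) = 1 - |H_c - Z_i| - N_c / K

where ``H_c`` is the cell's intrinsic habitat index, ``Z_i`` the fish's
preference value, ``N_c`` the cell's occupancy in the step-start snapshot
and ``K`` the carrying capacity.  ``N_c`` is the plain headcount for both
cells: the focal fish is part of its current cell's count but not the
candidate's.  An unconstrained fish therefore keeps wandering within a
plateau of equally preferred cells instead of freezing in place, which
keeps local densities equalizing even when ``K`` is small.

The demographic update runs reproduction first (each fish spawns one
age-1 recruit with probability R_i, placed in the mother's cell), then
survival (one Bernoulli draw per fish at total mortality M_i + F_i), then
ageing: survivors move up one class and redraw their preference from the
new class's niche; no fish outlives class 9.

The annual record — abundance by (cell, age class) — is captured after
the year's last movement step, before reproduction and survival.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .demography import FISHING_SCHEDULE, VitalRates, make_vital_rates
from .landscape import (
    LandscapeGrid,
    make_fragmented_landscape,
    make_gradient_landscape,
    neighbor_table,
)
from .niche import N_AGE_CLASSES, NicheModel, draw_preferences

#: The six carrying capacities of the study design.
CARRYING_CAPACITIES = (5, 10, 20, 40, 80, 160)
PREFERENCE_MODES = ("strong", "weak")
LANDSCAPE_STRUCTURES = ("gradient", "fragmented")

__all__ = [
    "CARRYING_CAPACITIES",
    "PREFERENCE_MODES",
    "LANDSCAPE_STRUCTURES",
    "AgentState",
    "SimConfig",
    "SimOutput",
    "GridLevels",
    "realized_suitability",
    "initialize_population",
    "movement_step",
    "annual_demographic_update",
    "run_simulation",
    "enumerate_scenarios",
    "run_scenario_grid",
    "scenario_code",
    "simulation_rng",
]


@dataclass
class AgentState:
    """The population at an instant: parallel per-fish arrays."""

    ages: np.ndarray  # age class 1..9
    preference: np.ndarray  # Z in [0, 1]
    cell: np.ndarray  # flat row-major cell index

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=np.int64)
        self.preference = np.asarray(self.preference, dtype=float)
        self.cell = np.asarray(self.cell, dtype=np.int64)
        if not (len(self.ages) == len(self.preference) == len(self.cell)):
            raise ValueError("per-fish arrays must have equal length")

    def __len__(self) -> int:
        return len(self.ages)

    def occupancy(self, n_cells: int) -> np.ndarray:
        """Headcount per cell, N_c."""
        return np.bincount(self.cell, minlength=n_cells)


@dataclass(frozen=True)
class SimConfig:
    """One simulation run's scenario and bookkeeping parameters."""

    preference: str = "strong"
    fishing_mortality: float = 0.0
    landscape: str = "gradient"
    carrying_capacity: float = 40.0
    years: int = 15
    steps_per_year: int = 40
    initial_per_age: int = 100
    seed: int = 0
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.preference not in PREFERENCE_MODES:
            raise ValueError(f"unknown preference mode {self.preference!r}")
        if self.landscape not in LANDSCAPE_STRUCTURES:
            raise ValueError(f"unknown landscape structure {self.landscape!r}")
        if self.carrying_capacity <= 0:
            raise ValueError("carrying_capacity must be positive")
        if self.years < 1 or self.steps_per_year < 0 or self.initial_per_age < 1:
            raise ValueError("years/steps_per_year/initial_per_age out of range")


@dataclass
class SimOutput:
    """Per-year snapshots of abundance by (cell, age class), plus metadata."""

    config: SimConfig
    abundance: np.ndarray  # (years, n_cells, n_ages) int
    grid_shape: tuple[int, int]
    extinct_year: int | None = None  # first year with zero fish, if any

    @property
    def years(self) -> int:
        return self.abundance.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Tidy long table: year, row, col, age_class, abundance (>0 rows)."""
        years, n_cells, n_ages = self.abundance.shape
        yy, cc, aa = np.nonzero(self.abundance)
        return pd.DataFrame(
            {
                "year": yy + 1,
                "row": cc // self.grid_shape[1],
                "col": cc % self.grid_shape[1],
                "age_class": aa + 1,
                "abundance": self.abundance[yy, cc, aa],
            }
        )


def realized_suitability(h, z, n, k) -> np.ndarray | float:
    """Basin-model realized habitat suitability ``1 - |H - Z| - N/K``.

    May be negative; only its ordering matters to the movement rule.
    """
    if np.any(np.asarray(k) <= 0):
        raise ValueError("carrying capacity K must be positive")
    return 1.0 - np.abs(np.asarray(h) - np.asarray(z)) - np.asarray(n) / np.asarray(k)


def initialize_population(
    config: SimConfig,
    model: NicheModel,
    grid: LandscapeGrid,
    rng: np.random.Generator,
) -> AgentState:
    """``initial_per_age`` fish per age class, in uniformly random cells,
    each with a preference drawn from its age's niche."""
    ages = np.repeat(np.arange(1, N_AGE_CLASSES + 1), config.initial_per_age)
    cells = rng.integers(0, grid.n_cells, size=len(ages))
    z = draw_preferences(model, ages, rng)
    return AgentState(ages, z, cells)


def movement_step(
    state: AgentState,
    grid: LandscapeGrid,
    rng: np.random.Generator,
    _nbr: tuple[np.ndarray, np.ndarray] | None = None,
) -> AgentState:
    """One synchronous movement step; returns the updated state.

    Ages, preferences and headcount are untouched; every displacement is at
    most one cell in Chebyshev distance.
    """
    if len(state) == 0:
        return state
    if _nbr is None:
        _nbr = neighbor_table(grid.height, grid.width)
    nbr_cells, nbr_counts = _nbr
    h = grid.habitat_flat
    k = grid.carrying_capacity
    occ = state.occupancy(grid.n_cells)

    pick = rng.integers(0, nbr_counts[state.cell])
    cand = nbr_cells[state.cell, pick]
    r_here = 1.0 - np.abs(h[state.cell] - state.preference) - occ[state.cell] / k
    r_there = 1.0 - np.abs(h[cand] - state.preference) - occ[cand] / k
    new_cell = np.where(r_there > r_here, cand, state.cell)
    return AgentState(state.ages, state.preference, new_cell)


def annual_demographic_update(
    state: AgentState,
    vr: VitalRates,
    model: NicheModel,
    rng: np.random.Generator,
) -> AgentState:
    """Reproduction, then survival, then ageing with preference redraw."""
    n = len(state)
    if n == 0:
        return state
    idx = state.ages - 1

    mothers = rng.random(n) < vr.reproduction[idx]
    newborn_cells = state.cell[mothers]

    survives = rng.random(n) >= vr.total_mortality[idx]
    survives &= state.ages < N_AGE_CLASSES  # class 9 never carries over
    aged = state.ages[survives] + 1
    aged_cells = state.cell[survives]
    aged_z = draw_preferences(model, aged, rng)

    n_born = len(newborn_cells)
    ages = np.concatenate([aged, np.ones(n_born, dtype=np.int64)])
    z = np.concatenate(
        [aged_z, draw_preferences(model, np.ones(n_born, dtype=np.int64), rng)]
    )
    cells = np.concatenate([aged_cells, newborn_cells])
    return AgentState(ages, z, cells)


def scenario_code(config: SimConfig) -> int:
    """Stable 31-bit code for a scenario (preference, F, landscape, K)."""
    key = (
        config.preference,
        round(float(config.fishing_mortality), 6),
        config.landscape,
        round(float(config.carrying_capacity), 6),
    )
    return zlib.crc32(repr(key).encode()) & 0x7FFFFFFF


def simulation_rng(config: SimConfig) -> np.random.Generator:
    """The run's random stream, determined by (seed, scenario, replicate).

    Stand-alone runs of a single replicate therefore reproduce the same
    replicate of a full grid run bit for bit.
    """
    ss = np.random.SeedSequence(
        [int(config.seed) & 0x7FFFFFFF, scenario_code(config), int(config.replicate)]
    )
    return np.random.default_rng(ss)


def _count_cells_by_age(state: AgentState, n_cells: int) -> np.ndarray:
    flat = state.cell * N_AGE_CLASSES + (state.ages - 1)
    return np.bincount(flat, minlength=n_cells * N_AGE_CLASSES).reshape(
        n_cells, N_AGE_CLASSES
    )


def build_landscape(config: SimConfig, rng: np.random.Generator) -> LandscapeGrid:
    """The run's landscape; fragmented layouts are drawn from ``rng``, so
    every replicate gets its own random arrangement."""
    if config.landscape == "gradient":
        return make_gradient_landscape(config.carrying_capacity)
    return make_fragmented_landscape(config.carrying_capacity, rng)


def run_simulation(config: SimConfig) -> SimOutput:
    """Run one replicate: ``years`` x (movement steps + demographic update).

    If the population dies out, the remaining annual records stay zero and
    ``extinct_year`` flags the first empty year.
    """
    rng = simulation_rng(config)
    model = NicheModel.from_mode(config.preference)
    grid = build_landscape(config, rng)
    vr = make_vital_rates(config.fishing_mortality)
    nbr = neighbor_table(grid.height, grid.width)

    state = initialize_population(config, model, grid, rng)
    records = np.zeros((config.years, grid.n_cells, N_AGE_CLASSES), dtype=np.int64)
    extinct_year = None
    for year in range(config.years):
        if len(state) == 0:
            extinct_year = year + 1
            break
        for _ in range(config.steps_per_year):
            state = movement_step(state, grid, rng, nbr)
        records[year] = _count_cells_by_age(state, grid.n_cells)
        state = annual_demographic_update(state, vr, model, rng)
    return SimOutput(
        config=config,
        abundance=records,
        grid_shape=(grid.height, grid.width),
        extinct_year=extinct_year,
    )


@dataclass(frozen=True)
class GridLevels:
    """The factor levels of the factorial simulation experiment."""

    preferences: tuple[str, ...] = PREFERENCE_MODES
    fishing_mortalities: tuple[float, ...] = FISHING_SCHEDULE
    landscapes: tuple[str, ...] = LANDSCAPE_STRUCTURES
    carrying_capacities: tuple[float, ...] = CARRYING_CAPACITIES


def enumerate_scenarios(
    levels: GridLevels | None = None, seed: int = 0, **config_kwargs
) -> list[SimConfig]:
    """Full factorial of the configured levels (default: the 144-scenario
    study design), as replicate-0 configs."""
    levels = levels or GridLevels()
    return [
        SimConfig(
            preference=p,
            landscape=l,
            carrying_capacity=k,
            fishing_mortality=f,
            seed=seed,
            **config_kwargs,
        )
        for p, l, k, f in itertools.product(
            levels.preferences,
            levels.landscapes,
            levels.carrying_capacities,
            levels.fishing_mortalities,
        )
    ]


def run_scenario_grid(
    levels: GridLevels | None = None,
    replicates: int = 60,
    master_seed: int = 0,
    window: tuple[int, int] | None = None,
    progress: bool = False,
    **config_kwargs,
) -> pd.DataFrame:
    """Run the factorial experiment and return one summary row per
    (scenario, replicate).

    Columns: the scenario factors, ``replicate``, ``mean_shannon``,
    ``mean_cv``, ``mean_popsize`` and ``extinct``.
    """
    from .summaries import DEFAULT_WINDOW, clip_window, summarize_replicate

    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    scenarios = enumerate_scenarios(levels, seed=master_seed, **config_kwargs)
    window = clip_window(window or DEFAULT_WINDOW, scenarios[0].years)
    rows = []
    iterator = scenarios
    if progress:
        from tqdm import tqdm  # pragma: no cover - cosmetic

        iterator = tqdm(scenarios)
    for scenario in iterator:
        for rep in range(replicates):
            config = replace(scenario, replicate=rep)
            out = run_simulation(config)
            rows.append(summarize_replicate(out, window).to_dict())
    return pd.DataFrame(rows)
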