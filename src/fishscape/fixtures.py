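"""Deterministic miniature worlds for exercising single rules in isolation.

These tiny grids (down to 1x2 cells) with hand-placed fish and degenerate
vital rates let the movement and demographic rules be checked without
stochasticity; they are not valid study landscapes.
"""

from __future__ import annotations

import numpy as np

from .demography import VitalRates
from .engine import AgentState
from .landscape import LandscapeGrid
from .niche import N_AGE_CLASSES

__all__ = ["make_fixture_world"]


def make_fixture_world(
    habitat,
    fish: list[tuple[int, float, tuple[int, int]]],
    carrying_capacity: float = 1e9,
    reproduction: float = 0.0,
    natural_mortality: float = 0.0,
    fishing_mortality: float = 0.0,
) -> tuple[LandscapeGrid, AgentState, VitalRates]:
    """Build a (grid, state, rates) triple for rule-level tests.

    Parameters
    ----------
    habitat
        2-D array-like of habitat indices; at least 1x2.
    fish
        List of ``(age_class, preference, (row, col))`` tuples.
    carrying_capacity
        Defaults to a huge K so density dependence is negligible.
    reproduction, natural_mortality, fishing_mortality
        Scalars applied uniformly to all nine age classes (degenerate
        rates such as 0 or 1 isolate single demographic pathways).
    """
    h = np.atleast_2d(np.asarray(habitat, dtype=float))
    grid = LandscapeGrid(h, carrying_capacity, structure="custom")
    ages = np.array([a for a, _, _ in fish], dtype=np.int64)
    z = np.array([p for _, p, _ in fish], dtype=float)
    cells = np.array([r * grid.width + c for _, _, (r, c) in fish], dtype=np.int64)
    if len(cells) and (cells.min() < 0 or cells.max() >= grid.n_cells):
        raise ValueError("fixture fish placed off-grid")
    state = AgentState(ages, z, cells)
    vr = VitalRates(
        np.full(N_AGE_CLASSES, float(reproduction)),
        np.full(N_AGE_CLASSES, float(natural_mortality)),
        np.full(N_AGE_CLASSES, float(fishing_mortality)),
    )
    return grid, state, vr
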