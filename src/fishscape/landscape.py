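"""Habitat landscapes on a closed-boundary 2-D lattice.

The standard landscape is an 11x11 grid in which each cell carries an
intrinsic habitat index ``H`` drawn from the eleven evenly spaced levels
0.0, 0.1, ..., 1.0, with each level assigned to exactly eleven cells.  The
same multiset of indices is arranged either as a smooth *gradient* (columns
carry the gradient, ``H = col / 10``) or as a uniformly random permutation
(*fragmented*).  All cells share a single environmental carrying capacity
``K`` which scales the density-dependence term of the habitat-selection
rule.  The boundary is closed: neighborhoods never wrap.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

GRID_SIZE = 11
#: The eleven admissible habitat-index levels, 0.0 .. 1.0 in steps of 0.1.
HABITAT_LEVELS = np.round(np.arange(GRID_SIZE) / 10.0, 1)

__all__ = [
    "GRID_SIZE",
    "HABITAT_LEVELS",
    "LandscapeGrid",
    "make_gradient_landscape",
    "make_fragmented_landscape",
    "moore_neighbors",
    "neighbor_table",
    "landscape_from_csv",
]


@dataclass(frozen=True)
class LandscapeGrid:
    """A rectangular lattice of habitat cells.

    Parameters
    ----------
    habitat_index
        2-D array of intrinsic habitat quality, one value per cell.
    carrying_capacity
        Positive scalar ``K`` shared by every cell.
    structure
        ``"gradient"``, ``"fragmented"``, or ``"custom"`` for test worlds.
    """

    habitat_index: np.ndarray
    carrying_capacity: float
    structure: str = "custom"

    def __post_init__(self) -> None:
        h = np.asarray(self.habitat_index, dtype=float)
        if h.ndim != 2 or h.size < 2:
            raise ValueError("habitat_index must be a 2-D array with >= 2 cells")
        if not np.isfinite(self.carrying_capacity) or self.carrying_capacity <= 0:
            raise ValueError(
                f"carrying_capacity must be positive, got {self.carrying_capacity!r}"
            )
        h = h.copy()
        h.setflags(write=False)
        object.__setattr__(self, "habitat_index", h)

    @property
    def height(self) -> int:
        return self.habitat_index.shape[0]

    @property
    def width(self) -> int:
        return self.habitat_index.shape[1]

    @property
    def n_cells(self) -> int:
        return self.habitat_index.size

    @property
    def habitat_flat(self) -> np.ndarray:
        """Habitat indices as a flat (row-major) vector."""
        return self.habitat_index.ravel()

    def to_frame(self) -> pd.DataFrame:
        """Tidy table with 0-based ``row``, ``col`` and ``H`` columns."""
        rows, cols = np.indices(self.habitat_index.shape)
        return pd.DataFrame(
            {"row": rows.ravel(), "col": cols.ravel(), "H": self.habitat_flat}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _standard_multiset() -> np.ndarray:
    """The 121 habitat values: each of the 11 levels exactly 11 times."""
    return np.repeat(HABITAT_LEVELS, GRID_SIZE)


def make_gradient_landscape(carrying_capacity: float) -> LandscapeGrid:
    """Deterministic gradient landscape: column ``j`` has ``H = j / 10``.

    ``H`` changes monotonically along the column axis and is constant along
    the row axis, so each level fills exactly one column of 11 cells.
    """
    h = np.tile(HABITAT_LEVELS, (GRID_SIZE, 1))
    return LandscapeGrid(h, carrying_capacity, structure="gradient")


def make_fragmented_landscape(
    carrying_capacity: float, rng: np.random.Generator
) -> LandscapeGrid:
    """Fragmented landscape: the gradient's multiset of ``H`` values under a
    uniform random permutation drawn from ``rng``."""
    values = rng.permutation(_standard_multiset())
    h = values.reshape(GRID_SIZE, GRID_SIZE)
    return LandscapeGrid(h, carrying_capacity, structure="fragmented")


def landscape_from_csv(
    path, carrying_capacity: float, structure: str = "custom"
) -> LandscapeGrid:
    """Rebuild a landscape from a ``row, col, H`` table written by ``to_csv``."""
    df = pd.read_csv(path)
    n_rows = int(df["row"].max()) + 1
    n_cols = int(df["col"].max()) + 1
    h = np.full((n_rows, n_cols), np.nan)
    h[df["row"].to_numpy(), df["col"].to_numpy()] = df["H"].to_numpy()
    if np.isnan(h).any():
        raise ValueError("landscape CSV does not cover every cell")
    return LandscapeGrid(h, carrying_capacity, structure=structure)


def moore_neighbors(grid: LandscapeGrid, cell: tuple[int, int]) -> list[tuple[int, int]]:
    """The up-to-8 cells at Chebyshev distance 1, without wrap-around."""
    r, c = cell
    if not (0 <= r < grid.height and 0 <= c < grid.width):
        raise ValueError(f"cell {cell!r} is off the {grid.height}x{grid.width} grid")
    out = []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            rr, cc = r + dr, c + dc
            if 0 <= rr < grid.height and 0 <= cc < grid.width:
                out.append((rr, cc))
    return out


@lru_cache(maxsize=None)
def neighbor_table(n_rows: int, n_cols: int) -> tuple[np.ndarray, np.ndarray]:
    """Flat-index Moore neighborhoods for every cell of an ``n_rows x n_cols``
    closed-boundary grid.

    Returns
    -------
    neighbors : (n_cells, 8) int array, padded with -1 past each cell's count
    counts : (n_cells,) int array of available-neighbor counts (3, 5 or 8)
    """
    n_cells = n_rows * n_cols
    nbrs = np.full((n_cells, 8), -1, dtype=np.int64)
    counts = np.zeros(n_cells, dtype=np.int64)
    for r in range(n_rows):
        for c in range(n_cols):
            i = r * n_cols + c
            k = 0
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == 0 and dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < n_rows and 0 <= cc < n_cols:
                        nbrs[i, k] = rr * n_cols + cc
                        k += 1
            counts[i] = k
    nbrs.setflags(write=False)
    counts.setflags(write=False)
    return nbrs, counts
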