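"""Age-specific habitat-preference niches.

Each of the nine age classes prefers a band of the habitat axis [0, 1].
A class's niche is a symmetric Beta(1.2, 1.2) density rescaled onto the
interval ``center ± width/2``; the nine centers are evenly spaced.  Two
preference regimes are modelled:

* **strong** — centers run 0.2 to 0.8 with width 0.4: narrow, well
  separated niches (strong ontogenetic niche shift);
* **weak** — centers run 0.4 to 0.6 with width 0.8: broad, heavily
  overlapping niches.

Under both regimes the union of the nine niche intervals is exactly
[0, 1], so the population's potential range is identical and only the
degree of between-age segregation differs.  An individual's preference
value ``Z`` is a single draw from its age's scaled Beta; it is redrawn
whenever the fish ages into the next class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

N_AGE_CLASSES = 9

_MODE_PARAMS = {
    # mode: (first center, last center, niche width)
    "strong": (0.2, 0.8, 0.4),
    "weak": (0.4, 0.6, 0.8),
}

__all__ = [
    "N_AGE_CLASSES",
    "NicheModel",
    "niche_centers",
    "niche_interval",
    "draw_preference",
    "draw_preferences",
]


@dataclass(frozen=True)
class NicheModel:
    mode: str
    center_lo: float
    center_hi: float
    width: float
    n_ages: int = N_AGE_CLASSES
    beta_alpha: float = 1.2
    beta_beta: float = 1.2

    @classmethod
    def from_mode(cls, mode: str) -> "NicheModel":
        try:
            lo, hi, width = _MODE_PARAMS[mode]
        except KeyError:
            raise ValueError(
                f"unknown preference mode {mode!r}; expected one of {sorted(_MODE_PARAMS)}"
            ) from None
        return cls(mode=mode, center_lo=lo, center_hi=hi, width=width)

    def __post_init__(self) -> None:
        centers = np.linspace(self.center_lo, self.center_hi, self.n_ages)
        los = centers - self.width / 2
        his = centers + self.width / 2
        if los.min() < -1e-12 or his.max() > 1 + 1e-12:
            raise ValueError("niche intervals must lie within [0, 1]")
        # union of intervals must cover [0, 1] without gaps
        if abs(los.min()) > 1e-12 or abs(his.max() - 1) > 1e-12:
            raise ValueError("union of niche intervals must equal [0, 1]")
        if np.any(los[1:] > his[:-1] + 1e-12):
            raise ValueError("adjacent niche intervals must not leave gaps")

    @property
    def centers(self) -> np.ndarray:
        return np.linspace(self.center_lo, self.center_hi, self.n_ages)

    @property
    def interval_lo(self) -> np.ndarray:
        return self.centers - self.width / 2

    @property
    def interval_hi(self) -> np.ndarray:
        return self.centers + self.width / 2


def niche_centers(model: NicheModel) -> np.ndarray:
    """Evenly spaced niche centers, ascending with age class (length 9)."""
    return model.centers


def _check_age(model: NicheModel, age: int) -> None:
    if not 1 <= age <= model.n_ages:
        raise ValueError(f"age class must be in 1..{model.n_ages}, got {age}")


def niche_interval(model: NicheModel, age: int) -> tuple[float, float]:
    """The support ``[center - width/2, center + width/2]`` of an age's niche."""
    _check_age(model, age)
    return float(model.interval_lo[age - 1]), float(model.interval_hi[age - 1])


def draw_preference(model: NicheModel, age: int, rng: np.random.Generator) -> float:
    """One preference value ``Z = lo + width * X`` with ``X ~ Beta(1.2, 1.2)``."""
    _check_age(model, age)
    x = rng.beta(model.beta_alpha, model.beta_beta)
    return float(model.interval_lo[age - 1] + model.width * x)


def draw_preferences(
    model: NicheModel, ages: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized preference draws, one per entry of ``ages`` (classes 1-9)."""
    ages = np.asarray(ages)
    if ages.size and (ages.min() < 1 or ages.max() > model.n_ages):
        raise ValueError("age classes must be in 1..9")
    x = rng.beta(model.beta_alpha, model.beta_beta, size=ages.shape)
    return model.interval_lo[ages - 1] + model.width * x
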