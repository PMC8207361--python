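"""Age-structured vital rates and their Leslie-matrix properties.

The population has nine age classes.  Annual reproduction is Bernoulli per
individual with age-specific probability R_i (R1 = 0.53, R2 = 0.50, then
0.01); newborn survival is 1, so R_i doubles as the recruitment rate.
Natural mortality M_i is 0.10 for ages 1-2, 0.40 for ages 3-8 and 1.0 for
age 9.  Size-selective fishing adds a flat mortality F to the exploited
ages 4-8, giving total mortalities of 40-90% across the 0-50% fishing
schedule.  These rates were chosen so that the unfished population is
almost stationary (leading eigenvalue ~0.9998) with a right-skewed age
structure, and so that fishing truncates the age structure while moving
total abundance comparatively little.

The Leslie matrix assembled from the rates provides deterministic oracles
for the stochastic engine: its leading eigenvalue is the asymptotic growth
rate and its dominant right eigenvector the stable age distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .niche import N_AGE_CLASSES

#: Age-4-8 fishing mortalities of the six study scenarios.
FISHING_SCHEDULE = (0.0, 0.10, 0.20, 0.30, 0.40, 0.50)
#: First (inclusive) and last (inclusive) exploited age class.
EXPLOITED_AGES = (4, 8)

_REPRODUCTION = np.array([0.53, 0.50, 0.01, 0.01, 0.01, 0.01, 0.01, 0.01, 0.01])
_NATURAL_MORTALITY = np.array([0.10, 0.10, 0.40, 0.40, 0.40, 0.40, 0.40, 0.40, 1.00])

__all__ = [
    "FISHING_SCHEDULE",
    "EXPLOITED_AGES",
    "VitalRates",
    "make_vital_rates",
    "build_leslie",
    "growth_rate",
    "euler_lotka_growth_rate",
    "stable_age_distribution",
]


@dataclass(frozen=True)
class VitalRates:
    """Per-age reproduction, natural mortality and fishing mortality."""

    reproduction: np.ndarray
    natural_mortality: np.ndarray
    fishing_mortality: np.ndarray
    n_ages: int = N_AGE_CLASSES

    def __post_init__(self) -> None:
        for name in ("reproduction", "natural_mortality", "fishing_mortality"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (self.n_ages,):
                raise ValueError(f"{name} must have shape ({self.n_ages},)")
            arr = arr.copy()
            arr.setflags(write=False)
            object.__setattr__(self, name, arr)
        if np.any(self.reproduction < 0) or np.any(self.reproduction > 1):
            raise ValueError("reproduction probabilities must lie in [0, 1]")
        total = self.natural_mortality + self.fishing_mortality
        if np.any(total < 0) or np.any(total > 1 + 1e-12):
            raise ValueError("total mortality M_i + F_i must lie in [0, 1] for every age")

    @property
    def total_mortality(self) -> np.ndarray:
        return self.natural_mortality + self.fishing_mortality

    @property
    def survival(self) -> np.ndarray:
        return 1.0 - self.total_mortality

    def to_dict(self) -> dict:
        return {
            "reproduction": self.reproduction.tolist(),
            "natural_mortality": self.natural_mortality.tolist(),
            "fishing_mortality": self.fishing_mortality.tolist(),
        }


def make_vital_rates(fishing_mortality: float = 0.0) -> VitalRates:
    """Standard vital rates with fishing mortality ``F`` on ages 4-8.

    ``F`` outside the six-scenario schedule {0, 0.1, ..., 0.5} is allowed
    but warned about; any ``F`` that pushes a total mortality past 1 is an
    error.
    """
    f = float(fishing_mortality)
    if not 0.0 <= f <= 0.5:
        if f < 0 or _NATURAL_MORTALITY[EXPLOITED_AGES[0] - 1] + f > 1:
            raise ValueError(f"fishing mortality {f} gives total mortality outside [0, 1]")
        warnings.warn(
            f"fishing mortality {f} is outside the study schedule {FISHING_SCHEDULE}",
            stacklevel=2,
        )
    fi = np.zeros(N_AGE_CLASSES)
    fi[EXPLOITED_AGES[0] - 1 : EXPLOITED_AGES[1]] = f
    return VitalRates(_REPRODUCTION, _NATURAL_MORTALITY, fi)


def build_leslie(vr: VitalRates) -> np.ndarray:
    """Leslie projection matrix: fecundities on the first row, survival
    probabilities ``1 - M_i - F_i`` on the subdiagonal."""
    n = vr.n_ages
    a = np.zeros((n, n))
    a[0, :] = vr.reproduction
    s = vr.survival
    a[np.arange(1, n), np.arange(n - 1)] = s[: n - 1]
    return a


def growth_rate(leslie: np.ndarray) -> float:
    """Asymptotic population growth rate: the dominant eigenvalue modulus."""
    eig = np.linalg.eigvals(leslie)
    return float(np.abs(eig).max())


def euler_lotka_growth_rate(leslie: np.ndarray, tol: float = 1e-12) -> float:
    """Dominant eigenvalue via bisection on the Euler-Lotka equation.

    Solves ``sum_i f_i l_i lam^{-i} = 1`` with ``l_1 = 1`` and
    ``l_{i+1} = l_i s_i`` (cumulative survivorship); this is the
    characteristic equation of the Leslie matrix and serves as an
    independent cross-check on the eigendecomposition.
    """
    f = np.asarray(leslie)[0]
    s = np.diag(leslie, k=-1)
    n = len(f)
    l = np.concatenate([[1.0], np.cumprod(s)])  # survivorship to each age

    def g(lam: float) -> float:
        return float(np.sum(f * l * lam ** -np.arange(1, n + 1))) - 1.0

    if not np.any(f * l > 0):
        return 0.0
    lo, hi = tol, 2.0
    while g(hi) > 0:  # g is decreasing in lam
        hi *= 2
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if g(mid) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def stable_age_distribution(leslie: np.ndarray) -> np.ndarray:
    """Stable age structure: the normalized dominant right eigenvector."""
    eig, vec = np.linalg.eig(leslie)
    i = int(np.argmax(np.abs(eig)))
    v = np.real(vec[:, i])
    v = np.abs(v)
    total = v.sum()
    if total == 0:
        raise ValueError("Leslie matrix has no positive stable age distribution")
    return v / total
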