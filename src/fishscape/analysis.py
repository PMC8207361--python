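"""Regression analyses linking spatial variability to age diversity.

For each (preference, landscape, K) combination an ordinary-least-squares
line of mean spatial CV on mean Shannon age diversity is fitted across the
pooled fishing levels and replicates.  The slope measures how strongly
spatial variability responds to age truncation: a negative slope means
that truncating the age structure (lower diversity) raises spatial
aggregation.  A full factorial model per landscape tests whether that
response is modulated jointly by preference regime and carrying capacity,
via the three-way interaction diversity x preference x K.

Carrying capacity enters the full model on a log2 scale by default (the
study levels 5..160 are geometric); a categorical coding is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

__all__ = [
    "SingularFitError",
    "RegressionResult",
    "fit_cv_vs_shannon",
    "slope_table",
    "factorial_model",
    "three_way_interaction",
]


class SingularFitError(ValueError):
    """Raised when a regression design is degenerate (e.g. constant predictor)."""


@dataclass(frozen=True)
class RegressionResult:
    """One CV ~ Shannon OLS fit for a factor combination."""

    preference: str | None
    landscape: str | None
    carrying_capacity: float | None
    slope: float
    slope_se: float
    intercept: float
    n_points: int
    p_value: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _combination_labels(points: pd.DataFrame) -> dict:
    labels = {}
    for col in ("preference", "landscape", "carrying_capacity"):
        if col in points.columns and points[col].nunique() == 1:
            labels[col] = points[col].iloc[0]
        else:
            labels[col] = None
    return labels


def fit_cv_vs_shannon(points: pd.DataFrame) -> RegressionResult:
    """OLS of ``mean_cv`` on ``mean_shannon`` for one factor combination.

    ``points`` needs ``mean_shannon`` and ``mean_cv`` columns; rows with
    missing indices (extinct-replicate NaNs) are dropped.  Raises
    :class:`SingularFitError` for < 3 usable points or a constant predictor.
    """
    pts = points.dropna(subset=["mean_shannon", "mean_cv"])
    if len(pts) < 3:
        raise SingularFitError(f"need >= 3 non-missing points, got {len(pts)}")
    x = pts["mean_shannon"].to_numpy(float)
    if np.allclose(x.var(), 0):
        raise SingularFitError("age-diversity predictor has zero variance")
    fit = smf.ols("mean_cv ~ mean_shannon", data=pts).fit()
    labels = _combination_labels(pts)
    return RegressionResult(
        preference=labels["preference"],
        landscape=labels["landscape"],
        carrying_capacity=labels["carrying_capacity"],
        slope=float(fit.params["mean_shannon"]),
        slope_se=float(fit.bse["mean_shannon"]),
        intercept=float(fit.params["Intercept"]),
        n_points=int(fit.nobs),
        p_value=float(fit.pvalues["mean_shannon"]),
    )


def slope_table(summaries: pd.DataFrame) -> pd.DataFrame:
    """One CV ~ Shannon slope +- SE per (preference, landscape, K).

    Fishing levels and replicates are pooled within each combination.
    Singular combinations are kept as rows with NaN estimates and a note
    in the ``error`` column.
    """
    rows = []
    keys = ["preference", "landscape", "carrying_capacity"]
    for (pref, land, k), grp in summaries.groupby(keys, sort=True):
        row = {"preference": pref, "landscape": land, "carrying_capacity": k}
        try:
            res = fit_cv_vs_shannon(grp)
            row.update(
                slope=res.slope,
                slope_se=res.slope_se,
                intercept=res.intercept,
                n_points=res.n_points,
                p_value=res.p_value,
                error="",
            )
        except SingularFitError as exc:
            row.update(
                slope=np.nan,
                slope_se=np.nan,
                intercept=np.nan,
                n_points=len(grp.dropna(subset=["mean_shannon", "mean_cv"])),
                p_value=np.nan,
                error=str(exc),
            )
        rows.append(row)
    return pd.DataFrame(rows)


def factorial_model(summaries: pd.DataFrame, k_coding: str = "log2"):
    """Full OLS model for one landscape with the three-way interaction
    ``mean_shannon x preference x K`` and all lower-order terms.

    ``k_coding`` is ``"log2"`` (continuous log2 K, default) or
    ``"categorical"``.  Returns the fitted statsmodels results object.
    """
    data = summaries.dropna(subset=["mean_shannon", "mean_cv"]).copy()
    if data["landscape"].nunique() > 1:
        raise ValueError("fit the factorial model separately per landscape")
    for col in ("preference", "carrying_capacity"):
        if data[col].nunique() < 2:
            raise ValueError(f"need >= 2 levels of {col}, got {data[col].nunique()}")
    if k_coding == "log2":
        data["K"] = np.log2(data["carrying_capacity"].astype(float))
        k_term = "K"
    elif k_coding == "categorical":
        k_term = "C(carrying_capacity)"
    else:
        raise ValueError(f"unknown k_coding {k_coding!r}")
    formula = f"mean_cv ~ mean_shannon * C(preference) * {k_term}"
    fit = smf.ols(formula, data=data).fit()
    if np.linalg.matrix_rank(fit.model.exog) < fit.model.exog.shape[1]:
        aliased = [
            name
            for name, p in zip(fit.model.exog_names, np.isnan(fit.bse) | (fit.bse == 0))
            if p
        ]
        raise SingularFitError(f"rank-deficient design; aliased terms: {aliased}")
    return fit


def three_way_interaction(fit) -> pd.DataFrame:
    """Coefficient, t and p of the diversity x preference x K term(s)."""
    names = [
        n
        for n in fit.params.index
        if "mean_shannon" in n and "preference" in n and ("K" in n or "carrying" in n)
    ]
    if not names:
        raise ValueError("fit has no three-way interaction term")
    return pd.DataFrame(
        {
            "coef": fit.params[names],
            "t": fit.tvalues[names],
            "p": fit.pvalues[names],
        }
    )
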